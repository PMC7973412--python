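"""Association-scan tests: kinship, score test, FDR, QTL declaration."""

import numpy as np
import pandas as pd
import pytest

from svqtl import (
    SignificanceRule,
    association_scan,
    bh_fdr,
    declare_qtl,
    genomic_inflation,
    kinship_matrix,
)
from svqtl.genotypes import CALL_A, CALL_B, CALL_MISSING
from svqtl.ldblocks import LDBlock

from conftest import toy_matrix

A, B, NA = CALL_A, CALL_B, CALL_MISSING


class TestKinship:
    def test_identical_and_complementary_individuals(self):
        calls = np.array([[A, B], [B, A], [A, B], [B, A]], dtype=np.int8)
        g = toy_matrix(calls)
        k = kinship_matrix(g)
        assert k.iloc[0, 0] == 1.0
        assert k.iloc[0, 1] == 0.0  # complementary homozygotes share nothing

    def test_hand_computed_sharing(self):
        # 3 individuals x 4 markers; sharing counted by hand
        calls = np.array(
            [[A, A, B], [A, B, B], [B, B, B], [A, A, A]], dtype=np.int8
        )  # markers x individuals
        g = toy_matrix(calls)
        k = kinship_matrix(g)
        # i1=(A,A,B,A), i2=(A,B,B,A): share m1, m3, m4 -> 3/4
        assert k.iloc[0, 1] == pytest.approx(0.75)
        # i1 vs i3=(B,B,B,A): share m3, m4 -> 2/4
        assert k.iloc[0, 2] == pytest.approx(0.5)
        # i2 vs i3: share m2, m3, m4 -> 3/4
        assert k.iloc[1, 2] == pytest.approx(0.75)
        np.testing.assert_allclose(k.to_numpy(), k.to_numpy().T)

    def test_all_missing_individual_rejected(self):
        calls = np.array([[A, NA], [B, NA]], dtype=np.int8)
        with pytest.raises(ValueError, match="no called genotypes"):
            kinship_matrix(toy_matrix(calls))


class TestScan:
    def test_perfect_association_is_overwhelming(self):
        rng = np.random.default_rng(1)
        dose = rng.integers(0, 2, 100).astype(np.int8)
        calls = np.vstack([dose, rng.integers(0, 2, 100, dtype=np.int8)])
        g = toy_matrix(calls)
        y = pd.Series(dose.astype(float), index=g.individual_ids)
        res = association_scan(g, y, kinship=None, n_pcs=0)
        assert res.set_index("marker").loc["m1", "p"] < 1e-10

    def test_r2_formula_value(self):
        # R2 = chi/(n-2+chi): chi=18, n=352 -> 18/368
        chi, n = 18.0, 352
        assert chi / (n - 2 + chi) == pytest.approx(0.0489, abs=5e-5)

    def test_reduces_to_marker_regression_with_identity_kinship(self):
        rng = np.random.default_rng(2)
        n = 80
        calls = rng.integers(0, 2, size=(12, n)).astype(np.int8)
        g = toy_matrix(calls)
        y = rng.normal(size=n) + 0.8 * calls[3]
        res = association_scan(g, pd.Series(y, index=g.individual_ids), None, n_pcs=0)
        # oracle: OLS score chi2 with REML variance, computed directly
        X = np.ones((n, 1))
        M = np.eye(n) - X @ np.linalg.inv(X.T @ X) @ X.T
        r = M @ y
        rss = float(r @ r)
        for mi, marker in enumerate(g.marker_ids):
            x = calls[mi].astype(float)
            gm = M @ x
            if gm @ gm < 1e-12:
                continue
            chi = (x @ r) ** 2 * (n - 1) / ((gm @ gm) * rss)
            assert res.set_index("marker").loc[marker, "chi2"] == pytest.approx(chi, rel=1e-6)

    def test_constant_phenotype_rejected(self):
        g = toy_matrix(np.array([[A, B, A, B]], dtype=np.int8))
        y = pd.Series(1.0, index=g.individual_ids)
        with pytest.raises(ValueError, match="constant"):
            association_scan(g, y)

    def test_missing_genotypes_reduce_per_marker_n(self):
        rng = np.random.default_rng(3)
        calls = rng.integers(0, 2, size=(2, 50)).astype(np.int8)
        calls[0, :5] = NA
        g = toy_matrix(calls)
        y = pd.Series(rng.normal(size=50), index=g.individual_ids)
        res = association_scan(g, y, None, n_pcs=0).set_index("marker")
        assert res.loc["m1", "n"] == 45
        assert res.loc["m2", "n"] == 50


class TestBHFDR:
    def test_step_up_matches_hand_oracle(self):
        # by hand: q_i = min_{j>=i} p_(j) * m / j
        q = bh_fdr([0.001, 0.02, 0.03, 0.5])
        np.testing.assert_allclose(q, [0.004, 0.04, 0.04, 0.5])

    def test_equal_and_single_pvalues_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])
        np.testing.assert_allclose(bh_fdr([0.07]), [0.07])

    def test_random_vectors_match_hand_step_up(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            p = rng.uniform(1e-6, 1, size=20)
            order = np.argsort(p)
            m = len(p)
            q_sorted = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
            expected = np.empty(m)
            expected[order] = np.minimum(q_sorted, 1.0)
            np.testing.assert_allclose(bh_fdr(p), expected)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5])
        with pytest.raises(ValueError):
            bh_fdr([1.5])


def _fake_results(marker_env_q: dict, bp=500_000, chrom="A01"):
    """results frames for declare_qtl; marker_env_q: env -> {marker: q}."""
    out = {}
    for env, markers in marker_env_q.items():
        rows = [
            {"marker": m, "chrom": chrom, "bp": bp + 1000 * i, "q": q, "p": q / 2}
            for i, (m, q) in enumerate(markers.items())
        ]
        out[env] = pd.DataFrame(rows)
    return out


class TestDeclareQTL:
    def test_marker_significant_in_two_environments_declares_qtl(self):
        results = _fake_results(
            {
                "E1": {"mA": 0.05},
                "E2": {"mA": 0.08},
                "E3": {"mA": 0.5},
                "E4": {"mA": 0.9},
                "E5": {"mA": 0.7},
            }
        )
        blocks = [LDBlock("A01", 400_000, 600_000, ["mA"])]
        qtls = declare_qtl(results, SignificanceRule(), blocks)
        assert len(qtls) == 1
        assert qtls.iloc[0]["size_kb"] == pytest.approx(200.0)
        assert set(qtls.iloc[0]["environments"].split(",")) == {"E1", "E2"}

    def test_single_environment_hit_is_not_a_qtl(self):
        results = _fake_results({f"E{i}": {"mA": 0.05 if i == 1 else 0.9} for i in range(1, 6)})
        blocks = [LDBlock("A01", 400_000, 600_000, ["mA"])]
        assert declare_qtl(results, SignificanceRule(), blocks).empty

    def test_without_blocks_point_qtl_with_warning(self):
        results = _fake_results({"E1": {"mA": 0.01}, "E2": {"mA": 0.01}})
        with pytest.warns(UserWarning, match="no LD blocks"):
            qtls = declare_qtl(results, SignificanceRule(), None)
        assert len(qtls) == 1 and qtls.iloc[0]["size_kb"] == 0.0

    def test_too_few_environments_rejected(self):
        results = _fake_results({"E1": {"mA": 0.01}})
        with pytest.raises(ValueError, match="environments"):
            declare_qtl(results, SignificanceRule(), None)


class TestCalibration:
    def test_r2_monotone_in_chi(self):
        n = 352
        chis = np.linspace(0, 500, 100)
        r2 = chis / (n - 2 + chis)
        assert np.all(np.diff(r2) > 0) and r2[0] == 0.0 and r2[-1] < 1.0

    def test_adjustment_restores_calibration_under_structure(self, nam_population):
        # family-structured phenotype, no causal marker: adjusted scan is
        # calibrated, unadjusted scan is inflated
        pop = nam_population
        rng = np.random.default_rng(5)
        fams = pop.subfamilies.unique()
        fam_eff = dict(zip(fams, rng.normal(0.0, 1.0, len(fams))))
        y = pd.Series(
            pop.subfamilies.map(fam_eff).to_numpy() + rng.normal(0.0, 1.0, 354),
            index=pop.individual_ids,
        )
        kin = kinship_matrix(pop.genotypes)
        adjusted = association_scan(pop.genotypes, y, kin, n_pcs=2)
        unadjusted = association_scan(pop.genotypes, y, None, n_pcs=0)
        # qualitative check at desk scale (the tight calibration bound is
        # asserted on a larger null study in the acceptance suite)
        assert genomic_inflation(adjusted["chi2"]) < 1.3
        assert genomic_inflation(unadjusted["chi2"]) > 1.5
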
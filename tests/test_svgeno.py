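"""PCR prediction, segregation chi-square, allelic effects and NMC tests."""

import numpy as np
import pandas as pd
import pytest

from svqtl import (
    DepthSimSpec,
    PCRAssay,
    SVRecord,
    allelic_effects,
    concordance,
    nmc_genotype,
    predict_amplicons,
    segregation_test,
    simulate_depth,
)
from svqtl.simulate import DepthTrack
from svqtl.svgeno import NO_PRODUCT

FOUNDER_ALLELES = {"P1": 0, "P2": 1}


def _assay(ref_len, chrom="A02", primer_len=20, left=10_000):
    right_start = left + ref_len - primer_len
    return PCRAssay("assay", chrom, (left, left + primer_len), (right_start, left + ref_len))


class TestAmplicons:
    def test_internal_deletion_shortens_product(self):
        assay = _assay(1924)
        sv = SVRecord("d", "A02", 10_100, 10_100 + 1361, "DEL", founder_alleles=FOUNDER_ALLELES)
        assert predict_amplicons(assay, sv) == {"ref": 1924, "alt": 563}

    def test_internal_insertion_lengthens_product(self):
        assay = _assay(262)
        sv = SVRecord("i", "A02", 10_100, 10_100, "INS", size=38, founder_alleles=FOUNDER_ALLELES)
        assert predict_amplicons(assay, sv) == {"ref": 262, "alt": 300}

    def test_primer_disrupting_deletion_gives_no_product(self):
        assay = _assay(819)
        # deletion overlapping the reverse-primer footprint
        sv = SVRecord("d", "A02", 10_810, 10_810 + 1313, "DEL")
        assert predict_amplicons(assay, sv)["alt"] == NO_PRODUCT

    def test_distant_sv_leaves_both_alleles_reference(self):
        assay = _assay(500)
        sv = SVRecord("d", "A02", 90_000, 90_400, "DEL")
        assert predict_amplicons(assay, sv) == {"ref": 500, "alt": 500}

    def test_other_chromosome_warns_and_is_reference_length(self):
        assay = _assay(500)
        sv = SVRecord("d", "C02", 10_100, 10_200, "DEL")
        with pytest.warns(UserWarning, match="another chromosome"):
            assert predict_amplicons(assay, sv) == {"ref": 500, "alt": 500}

    def test_deletion_size_conservation_for_internal_deletions(self):
        # reference length - deletion size = deletion-allele length
        for ref_len, del_size in [(1130, 373), (1924, 1361), (667, 35), (700, 500)]:
            assay = _assay(ref_len)
            sv = SVRecord("d", "A02", 10_050, 10_050 + del_size, "DEL")
            out = predict_amplicons(assay, sv)
            assert out["alt"] == ref_len - del_size


class TestSegregation:
    def test_derived_chi2_tail_value(self):
        t = segregation_test(50, 30)
        assert t.chi2 == pytest.approx(5.0)
        assert t.p == pytest.approx(0.0253, abs=5e-5)
        assert t.stars == "*"

    def test_balanced_counts_give_p_one(self):
        t = segregation_test(30, 30)
        assert t.p == pytest.approx(1.0)
        assert t.stars == ""

    def test_star_thresholds(self):
        assert segregation_test(43, 17).stars == "***"
        assert segregation_test(42, 17).stars == "**"
        assert segregation_test(36, 18).stars == "*"

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            segregation_test(0, 0)


class TestAllelicEffects:
    def _pheno(self, values_by_ind, env="E1"):
        rows = [
            {"individual": ind, "environment": env, "replicate": 1, "days": v}
            for ind, v in values_by_ind.items()
        ]
        return pd.DataFrame(rows)

    def test_hand_computed_t_test(self):
        pheno = self._pheno({"a": 10, "b": 11, "c": 12, "d": 13, "e": 14, "f": 15})
        geno = pd.Series({"a": 1, "b": 1, "c": 1, "d": 0, "e": 0, "f": 0})
        (eff,) = allelic_effects("sv", geno, pheno)
        assert eff.effect == pytest.approx(-3.0)
        assert eff.t == pytest.approx(-3.674, abs=2e-3)
        assert eff.p == pytest.approx(0.021, abs=2e-3)
        assert eff.significant

    def test_identical_means_give_null_effect(self):
        pheno = self._pheno({"a": 10, "b": 12, "c": 10, "d": 12})
        geno = pd.Series({"a": 1, "b": 1, "c": 0, "d": 0})
        (eff,) = allelic_effects("sv", geno, pheno)
        assert eff.effect == pytest.approx(0.0)
        assert eff.p == pytest.approx(1.0)
        assert not eff.significant

    def test_empty_class_marks_environment_untestable(self):
        pheno = self._pheno({"a": 10, "b": 12})
        geno = pd.Series({"a": 1, "b": 1})
        (eff,) = allelic_effects("sv", geno, pheno)
        assert not eff.testable and eff.effect is None

    def test_effect_recovery_across_seeds(self, nam_population):
        from svqtl import PhenotypeModel, simulate_phenotypes

        estimates = []
        for s in range(15):
            model = PhenotypeModel(qtl_effects={"SVX": -0.88}, var_ge=0.0, var_e=2.0)
            pheno = simulate_phenotypes(nam_population, model, n_env=5, n_reps=2, seed=500 + s)
            effs = allelic_effects("SVX", nam_population.sv_genotypes["SVX"], pheno)
            estimates.append(np.mean([e.effect for e in effs if e.testable]))
        assert np.mean(estimates) == pytest.approx(-0.88, abs=0.1)


class TestNMC:
    def test_threshold_partition(self):
        track = DepthTrack("A02", 0, np.concatenate([np.full(100, 30), np.full(50, 3), np.full(100, 30)]))
        call = nmc_genotype(track, (100, 150))
        assert call.nmc == pytest.approx(0.1)
        assert call.call == "deletion"
        flat = DepthTrack("A02", 0, np.full(300, 30))
        assert nmc_genotype(flat, (100, 150)).call == "ambiguous"
        high = DepthTrack("A02", 0, np.concatenate([np.full(100, 30), np.full(50, 60), np.full(100, 30)]))
        assert nmc_genotype(high, (100, 150)).call == "reference"

    def test_boundary_values_are_ambiguous(self):
        half = DepthTrack("A02", 0, np.concatenate([np.full(100, 30), np.full(50, 15), np.full(100, 30)]))
        assert nmc_genotype(half, (100, 150)).call == "ambiguous"

    def test_zero_baseline_is_uninformative_error(self):
        track = DepthTrack("A02", 0, np.concatenate([np.zeros(100, dtype=int), np.full(50, 10)]))
        with pytest.raises(ValueError, match="uninformative"):
            nmc_genotype(track, (100, 150))

    def test_simulated_panel_homozygous_accuracy(self):
        # diversity-panel screening convention: the duplicated baseline of
        # the modified reference halves per-copy flank depth, so reference
        # individuals score NMC ~ 2 and heterozygotes ~ 1
        spec = DepthSimSpec(mean_depth=30.0, dropout_rate=0.05)
        genotypes = {f"del{i}": "del" for i in range(60)}
        genotypes.update({f"ref{i}": "ref" for i in range(60)})
        genotypes.update({f"het{i}": "het" for i in range(60)})
        tracks = simulate_depth(genotypes, ("A02", 2_000, 2_288), ("A02", 0, 4_288), spec, seed=21)
        calls = {
            ind: nmc_genotype(t, (2_000, 2_288), individual=ind, baseline_copies=2)
            for ind, t in tracks.items()
        }
        hom_correct = sum(
            calls[i].call == ("deletion" if g == "del" else "reference")
            for i, g in genotypes.items()
            if g != "het"
        )
        assert hom_correct / 120 >= 0.99
        het_nmc = [calls[i].nmc for i, g in genotypes.items() if g == "het"]
        assert np.mean(het_nmc) == pytest.approx(1.0, abs=0.05)
        assert all(calls[i].call == "ambiguous" for i, g in genotypes.items() if g == "het")
        # single-copy baseline: heterozygote dosage puts NMC at 0.5
        plain = [
            nmc_genotype(t, (2_000, 2_288)).nmc
            for i, t in tracks.items()
            if genotypes[i] == "het"
        ]
        assert np.mean(plain) == pytest.approx(0.5, abs=0.05)


class TestConcordance:
    def test_identical_call_vectors_agree_fully(self):
        calls = {f"i{k}": "deletion" for k in range(5)}
        table, agreement = concordance(calls, calls)
        assert agreement == 1.0
        assert table.loc["deletion", "deletion"] == 5

    def test_one_discordant_of_ten(self):
        nmc = {f"i{k}": "deletion" for k in range(10)}
        pcr = dict(nmc)
        pcr["i9"] = "reference"
        _, agreement = concordance(nmc, pcr)
        assert agreement == pytest.approx(0.9)

    def test_heterozygotes_fall_in_ambiguous_row(self):
        spec = DepthSimSpec(mean_depth=30.0)
        genotypes = {f"het{i}": "het" for i in range(30)}
        tracks = simulate_depth(genotypes, ("A02", 2_000, 2_288), ("A02", 0, 4_288), spec, seed=22)
        nmc = {
            i: nmc_genotype(t, (2_000, 2_288), baseline_copies=2).call
            for i, t in tracks.items()
        }
        pcr = {i: "heterozygous" for i in genotypes}
        table, agreement = concordance(nmc, pcr)
        assert table.loc["ambiguous", "heterozygous"] == 30
        assert np.isnan(agreement)
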
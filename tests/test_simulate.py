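"""Simulation-module tests: meiosis model, DH laws, phenotype model, depth."""

import numpy as np
import pandas as pd
import pytest

from svqtl import (
    DepthSimSpec,
    GeneticMap,
    PhenotypeModel,
    SVLocusSpec,
    estimate_heritability,
    heritability_expected,
    inject_call_failures,
    make_dh_population,
    simulate_depth,
    simulate_founders,
    simulate_phenotypes,
)
from svqtl.genotypes import CALL_FAILED


@pytest.fixture(scope="module")
def one_chrom_map():
    # 100 markers over 100 cM (1 Mb at 100 cM/Mb): adjacent spacing 1 cM
    return GeneticMap.dense({"A01": 1_000_000}, spacing_bp=10_000, cm_per_mb=100.0)


@pytest.fixture(scope="module")
def big_pop(one_chrom_map):
    founders = simulate_founders(2, one_chrom_map, seed=1)
    # make the two parents complementary so gamete origin is observable
    founders.haplotypes["A01"][0, :] = 0
    founders.haplotypes["A01"][1, :] = 1
    return make_dh_population(founders, {"P2": 10_000}, seed=2)


class TestFounders:
    def test_polymorphic_sv_has_requested_carriers(self, small_map):
        sv = SVLocusSpec("s1", "A01", 500_000, 500_300, "DEL", n_carriers=3)
        f = simulate_founders(7, small_map, [sv], seed=3)
        assert f.sv_alleles["s1"].sum() == 3
        assert 0 < f.sv_alleles["s1"].sum() < 7

    def test_no_sv_loci_gives_empty_alleles(self, small_map):
        f = simulate_founders(2, small_map, seed=4)
        assert f.sv_alleles.empty or f.sv_alleles.shape[1] == 0
        assert set(f.haplotypes) == {"A01", "A02"}

    def test_same_seed_reproduces_founders_exactly(self, small_map):
        sv = SVLocusSpec("s1", "A01", 500_000, 500_300, "DEL", n_carriers=2)
        a = simulate_founders(7, small_map, [sv], seed=5)
        b = simulate_founders(7, small_map, [sv], seed=5)
        for chrom in a.haplotypes:
            np.testing.assert_array_equal(a.haplotypes[chrom], b.haplotypes[chrom])
        pd.testing.assert_frame_equal(a.sv_alleles, b.sv_alleles)

    def test_sv_outside_map_extent_rejected(self, small_map):
        sv = SVLocusSpec("s1", "A01", 5_000_000, 5_000_300, "DEL")
        with pytest.raises(ValueError, match="outside map extent"):
            simulate_founders(7, small_map, [sv], seed=6)
        sv2 = SVLocusSpec("s2", "Z99", 100, 400, "DEL")
        with pytest.raises(ValueError, match="not on the map"):
            simulate_founders(7, small_map, [sv2], seed=6)


class TestMeiosis:
    def test_every_dh_line_is_fully_homozygous(self, nam_population):
        # DH lines carry a single doubled gamete: calls are pure 0/1 alleles,
        # heterozygosity is structurally zero (no het state exists)
        assert set(np.unique(nam_population.genotypes.calls)) <= {0, 1}

    def test_mean_crossovers_match_map_length(self, big_pop):
        # 100 cM chromosome: Poisson mean 1 crossover per gamete; with
        # complementary parents each observable switch is a crossover
        calls = big_pop.genotypes.calls
        switches = (np.diff(calls, axis=0) != 0).sum(axis=0)
        assert switches.mean() == pytest.approx(1.0, abs=0.05)

    def test_within_subfamily_allele_frequency_is_half(self, big_pop):
        # binomial oracle: freq 0.5, 3 SE with n = 10,000 is +/- 0.015
        freq = (big_pop.genotypes.calls == 1).mean(axis=1)
        assert np.all(np.abs(freq - 0.5) < 0.015)

    def test_subfamily_sizes_default_to_study_design(self, nam_population):
        sizes = nam_population.subfamilies.value_counts()
        assert sorted(sizes) == [54, 60, 60, 60, 60, 60]
        assert nam_population.genotypes.n_individuals == 354

    def test_viability_weight_injects_segregation_distortion(self, small_map):
        founders = simulate_founders(2, small_map, seed=7)
        marker = founders.gmap.table.index[0]
        pop = make_dh_population(
            founders, {"P2": 400}, seed=8, viability={marker: (1, 0.3)}
        )
        row = pop.genotypes.calls[0]
        hap = founders.haplotypes["A01"][:, 0]
        if hap[0] == hap[1]:  # monomorphic marker: nothing to distort
            pytest.skip("marker monomorphic between the two founders")
        assert (row == 1).mean() < 0.4  # expected 0.3/(1+0.3) ~ 0.23


class TestPhenotypes:
    def test_noise_free_limit_reproduces_exact_effect(self, nam_population):
        model = PhenotypeModel(qtl_effects={"SVX": -0.88}, var_ge=0.0, var_e=0.0)
        pheno = simulate_phenotypes(nam_population, model, n_env=3, n_reps=1, seed=9)
        dose = nam_population.sv_genotypes["SVX"]
        for _, sub in pheno.groupby("environment"):
            means = sub.set_index("individual")["days"]
            diff = means[dose == 1].mean() - means[dose == 0].mean()
            assert diff == pytest.approx(-0.88, abs=1e-9)

    def test_null_model_variance_matches_residual(self, nam_population):
        model = PhenotypeModel(var_env=0.0, var_e=1.0)
        pheno = simulate_phenotypes(nam_population, model, n_env=2, n_reps=1, seed=10)
        for _, sub in pheno.groupby("environment"):
            assert sub["days"].var() == pytest.approx(1.0, rel=0.2)

    def test_closed_form_heritability_value(self):
        assert heritability_expected(1.953, 1.0, 2.0, 5, 2) == pytest.approx(0.830, abs=5e-4)

    def test_anova_estimate_recovers_expected_heritability(self, nam_population):
        model = PhenotypeModel(var_polygenic=1.953, var_ge=1.0, var_e=2.0)
        vals = [
            estimate_heritability(
                simulate_phenotypes(nam_population, model, n_env=5, n_reps=2, seed=100 + s)
            )["h2"]
            for s in range(10)
        ]
        assert np.mean(vals) == pytest.approx(0.83, abs=0.02)

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            PhenotypeModel(var_e=-1.0)

    def test_same_seed_reproduces_phenotypes(self, nam_population):
        model = PhenotypeModel(var_ge=0.5, var_e=1.0)
        a = simulate_phenotypes(nam_population, model, n_env=2, n_reps=2, seed=42)
        b = simulate_phenotypes(nam_population, model, n_env=2, n_reps=2, seed=42)
        pd.testing.assert_frame_equal(a, b)


class TestDepth:
    def test_dosage_scales_in_interval_depth(self):
        spec = DepthSimSpec(mean_depth=30.0, dropout_rate=0.05)
        region = ("A01", 0, 10_000)
        sv = ("A01", 4_000, 6_000)
        tracks = simulate_depth(
            {"hom": "del", "ref": "ref", "het": "het"}, sv, region, spec, seed=11
        )
        hom = tracks["hom"]
        assert hom.mean_over(4_000, 6_000) == pytest.approx(1.5, abs=0.3)
        ref = tracks["ref"]
        ratio = ref.mean_over(4_000, 6_000) / ref.mean_over(0, 4_000)
        assert ratio == pytest.approx(1.0, abs=0.1)
        het = tracks["het"]
        assert het.mean_over(4_000, 6_000) / het.mean_over(0, 4_000) == pytest.approx(0.5, abs=0.1)

    def test_dropout_rate_validated(self):
        with pytest.raises(ValueError):
            DepthSimSpec(dropout_rate=0.6)


class TestCallFailures:
    def test_failures_confined_to_carrier_subfamilies(self, nam_population):
        pop = nam_population
        svs = pop.founders.sv_records()
        injected = inject_call_failures(pop.genotypes, svs, pop.sv_genotypes)
        in_del = (
            (injected.markers["chrom"] == "A01")
            & (injected.markers["bp"] >= 900_000)
            & (injected.markers["bp"] < 900_288)
        ).to_numpy()
        assert in_del.sum() >= 1
        failed = injected.calls[in_del][0] == CALL_FAILED
        carriers = pop.sv_genotypes["SVX"].to_numpy() == 1
        np.testing.assert_array_equal(failed, carriers)
        # carriers only exist in subfamilies of carrier founders (pedigree oracle)
        carrier_fams = set(pop.subfamilies[carriers])
        assert carrier_fams <= {"P2", "P4", "P6"}

    def test_markers_outside_deletions_untouched(self, nam_population):
        pop = nam_population
        injected = inject_call_failures(pop.genotypes, pop.founders.sv_records(), pop.sv_genotypes)
        outside = ~(
            (injected.markers["chrom"] == "A01")
            & (injected.markers["bp"] >= 900_000)
            & (injected.markers["bp"] < 900_288)
        ).to_numpy()
        np.testing.assert_array_equal(injected.calls[outside], pop.genotypes.calls[outside])
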
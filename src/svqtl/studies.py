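"""Desk-scale simulation studies.

Each function runs a self-contained simulation experiment at the design of
the multiparental study this package models (354 DH lines in six
subfamilies from seven founders, five environments, two replicates) and
returns summary numbers:

* heritability: entry-mean broad-sense H2 from two-way ANOVA under
  genotypic / GxE / residual variances of 1.953 / 1.0 / 2.0 days^2
  (expected H2 = 0.830),
* allelic-effect recovery for a planted 288 bp deletion of -0.88 days,
* QTL-declaration power for the same deletion through the full scan
  (QC -> SNaP -> kinship+PC mixed-model scan -> LD blocks -> declaration),
* type-I calibration and genomic inflation of the scan under a
  family-structured null.

All randomness flows from the single ``seed`` argument through
``numpy.random.SeedSequence`` spawning, so every study is reproducible.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import pandas as pd

from .assoc import (
    SignificanceRule,
    association_scan,
    declare_qtl,
    genomic_inflation,
    kinship_matrix,
)
from .genotypes import GeneticMap, GenotypeMatrix
from .ldblocks import find_blocks
from .markers import call_snap, qc_filter
from .simulate import (
    PhenotypeModel,
    SVLocusSpec,
    entry_means,
    estimate_heritability,
    inject_call_failures,
    make_dh_population,
    simulate_founders,
    simulate_phenotypes,
    sv_marker_matrix,
)

#: Variance components used throughout: genotypic, GxE, residual (days^2).
H2_VARIANCES = (1.953, 1.0, 2.0)
PLANTED_EFFECT_DAYS = -0.88
N_ENV = 5
N_REPS = 2


def _spawn_seeds(seed: int, n: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(seed).spawn(n)


def _seed_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def _study_map(n_extra_chroms: int = 6) -> GeneticMap:
    sizes = {"A02": 3_000_000}
    for i in range(3, 3 + n_extra_chroms):
        sizes[f"A{i:02d}"] = 2_000_000
    return GeneticMap.dense(sizes, spacing_bp=50_000, cm_per_mb=2.0)


def _planted_sv() -> SVLocusSpec:
    return SVLocusSpec("SV_A02", "A02", 1_200_000, 1_200_288, "DEL", n_carriers=3)


def heritability_study(n_seeds: int = 20, seed: int = 0) -> dict:
    """Mean ANOVA H2 over replicate phenotype simulations (expected 0.830)."""
    var_g, var_ge, var_e = H2_VARIANCES
    gmap = GeneticMap.dense({"A02": 2_000_000})
    pop_seed, *pheno_seeds = _spawn_seeds(seed, n_seeds + 1)
    founders = simulate_founders(7, gmap, seed=_seed_int(pop_seed))
    pop = make_dh_population(founders, seed=_seed_int(pop_seed) + 1)
    model = PhenotypeModel(var_polygenic=var_g, var_ge=var_ge, var_e=var_e)
    values = []
    for ss in pheno_seeds:
        pheno = simulate_phenotypes(pop, model, n_env=N_ENV, n_reps=N_REPS, seed=_seed_int(ss))
        values.append(estimate_heritability(pheno)["h2"])
    return {"mean_h2": float(np.mean(values)), "values": values, "n": n_seeds}


def effect_recovery_study(n_seeds: int = 50, seed: int = 0) -> dict:
    """Mean environment-adjusted carrier-minus-reference effect estimate.

    One 354-line population with a fresh founder/carrier configuration per
    replicate; phenotype = environment effects + planted SV effect of
    -0.88 days + residual (sd 2 days).  The per-replicate estimate averages
    the per-environment differences in genotype-class means.
    """
    from .svgeno import allelic_effects

    gmap = GeneticMap.dense({"A02": 3_000_000}, spacing_bp=50_000, cm_per_mb=2.0)
    sv = _planted_sv()
    estimates = []
    for ss in _spawn_seeds(seed, n_seeds):
        base = _seed_int(ss)
        founders = simulate_founders(7, gmap, [sv], seed=base, block_cm=0.8)
        pop = make_dh_population(founders, seed=base + 1)
        model = PhenotypeModel(qtl_effects={sv.id: PLANTED_EFFECT_DAYS}, var_ge=0.0, var_e=2.0)
        pheno = simulate_phenotypes(pop, model, n_env=N_ENV, n_reps=N_REPS, seed=base + 2)
        effs = allelic_effects(sv.id, pop.sv_genotypes[sv.id], pheno)
        estimates.append(float(np.mean([e.effect for e in effs if e.testable])))
    return {"mean_effect": float(np.mean(estimates)), "values": estimates, "n": n_seeds}


def _scan_one_replicate(gmap: GeneticMap, sv: SVLocusSpec, base: int) -> bool:
    """One full-chain replicate; True when the planted locus is declared a QTL."""
    founders = simulate_founders(7, gmap, [sv], seed=base, block_cm=0.8)
    pop = make_dh_population(founders, seed=base + 1)
    model = PhenotypeModel(qtl_effects={sv.id: PLANTED_EFFECT_DAYS}, var_ge=0.0, var_e=2.0)
    pheno = simulate_phenotypes(pop, model, n_env=N_ENV, n_reps=N_REPS, seed=base + 2)
    raw = inject_call_failures(pop.genotypes, founders.sv_records(), pop.sv_genotypes)
    qc, _ = qc_filter(raw)
    _, snap = call_snap(raw)
    svm = sv_marker_matrix(pop)
    parts = [qc] + ([snap] if snap.n_markers else []) + [svm]
    calls = np.vstack([p.calls for p in parts])
    markers = pd.concat([p.markers[["chrom", "bp", "cm"]] for p in parts])
    g = GenotypeMatrix(calls, markers, qc.individuals.copy())
    kin = kinship_matrix(qc)
    means = entry_means(pheno)
    results = {
        env: association_scan(g, means[env], kin, n_pcs=2, environment=env)
        for env in means.columns
    }
    blocks = find_blocks(qc)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        qtls = declare_qtl(results, SignificanceRule(), blocks)
    return any(
        q.chrom == sv.chrom and q.start - 100_000 <= sv.start <= q.end + 100_000
        for q in qtls.itertuples()
    )


def qtl_power_study(n_seeds: int = 20, seed: int = 0) -> dict:
    """Fraction of replicates in which the planted deletion is declared a QTL
    (significant at FDR <= 0.1 in at least two of five environments)."""
    gmap = _study_map()
    sv = _planted_sv()
    found = [
        _scan_one_replicate(gmap, sv, _seed_int(ss)) for ss in _spawn_seeds(seed, n_seeds)
    ]
    return {"power": float(np.mean(found)), "values": found, "n": n_seeds}


def null_calibration_study(seed: int = 0, n_chroms: int = 10, markers_per_chrom: int = 80) -> dict:
    """Scan calibration under a family-structured null (no causal marker).

    The phenotype carries subfamily mean shifts (sd 1 day) plus residual
    noise; the kinship+PC-adjusted scan should show a 5% type-I rate at
    p < 0.05 and genomic inflation near 1, while the unadjusted scan on the
    same data is inflated.
    """
    base = _seed_int(np.random.SeedSequence(seed).spawn(1)[0])
    sizes = {f"A{i + 1:02d}": markers_per_chrom * 25_000 for i in range(n_chroms)}
    gmap = GeneticMap.dense(sizes, spacing_bp=25_000, cm_per_mb=4.0)
    founders = simulate_founders(7, gmap, seed=base)
    pop = make_dh_population(founders, seed=base + 1)
    rng = np.random.default_rng(base + 2)
    fams = list(pop.subfamilies.unique())
    fam_eff = dict(zip(fams, rng.normal(0.0, 1.0, len(fams))))
    y = pd.Series(
        pop.subfamilies.map(fam_eff).to_numpy() + rng.normal(0.0, 1.0, len(pop.individual_ids)),
        index=pop.individual_ids,
    )
    kin = kinship_matrix(pop.genotypes)
    adjusted = association_scan(pop.genotypes, y, kin, n_pcs=2)
    unadjusted = association_scan(pop.genotypes, y, None, n_pcs=0)
    return {
        "type1_rate": float((adjusted["p"] < 0.05).mean()),
        "lambda_adjusted": genomic_inflation(adjusted["chi2"]),
        "lambda_unadjusted": genomic_inflation(unadjusted["chi2"]),
        "n_markers": int(len(adjusted)),
    }
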
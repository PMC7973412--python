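"""End-to-end orchestration: simulate -> QC/SNaP -> GWAS -> LD blocks ->
SV catalog -> locus validation -> motif scan.

A :class:`PipelineConfig` holds every tunable threshold with the pipeline's
standard defaults (QC 10%/5%, FDR 0.1, suggestive -log10 p 3.0, at least 2
environments, 10 kb promoter windows, NMC 0.5/1.5, SNaP 0.10/0.05, Haploview
Gabriel parameters) plus the simulation design.  ``run_pipeline`` executes
the stages in dependency order into a run directory with per-stage
subfolders, a machine-readable manifest of record counts, and a copy of the
resolved configuration, so a run is reproducible from its output directory
alone.
"""

from __future__ import annotations

import dataclasses
import json
import os
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as svio
from .assoc import SignificanceRule, association_scan, declare_qtl, kinship_matrix
from .genotypes import GeneticMap
from .ldblocks import GabrielParams, blocks_table, find_blocks
from .markers import call_snap, qc_filter, snap_report
from .simulate import (
    DepthSimSpec,
    PhenotypeModel,
    SVLocusSpec,
    entry_means,
    estimate_heritability,
    inject_call_failures,
    make_dh_population,
    random_sequence,
    simulate_depth,
    simulate_founders,
    simulate_genes,
    simulate_phenotypes,
)
from .svcat import classify_polymorphism, intersect_genes, qtl_sv_report, size_classes
from .svgeno import (
    allelic_effects,
    concordance,
    effects_table,
    nmc_genotype,
    segregation_test,
)
from .tfbs import hits_table, make_pfm_from_consensus, scan


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class SimulationDesign:
    """Synthetic study design (defaults mirror the elite NAM-DH setting)."""

    n_founders: int = 7
    chrom_sizes_bp: dict = field(default_factory=lambda: {"A02": 3_000_000, "C02": 2_000_000})
    marker_spacing_bp: int = 50_000
    cm_per_mb: float = 2.0
    block_cm: Optional[float] = 0.8
    subfamily_size: int = 60
    short_subfamily_size: int = 54
    n_env: int = 5
    n_reps: int = 2
    grand_mean: float = 245.0
    var_polygenic: float = 1.5
    var_ge: float = 1.0
    var_e: float = 2.0
    sv_effect_days: float = -0.88
    sv_size_bp: int = 288
    sv_start_bp: int = 1_200_000
    sv_chrom: str = "A02"
    sv_n_carriers: int = 3
    mean_depth: float = 30.0
    dropout_rate: float = 0.05
    n_genes_per_chrom: int = 40
    flowering_fraction: float = 0.15


@dataclass
class PipelineConfig:
    """All stage toggles, thresholds and the seed for one run."""

    seed: int = 1
    design: SimulationDesign = field(default_factory=SimulationDesign)
    # stage toggles
    run_markers: bool = True
    run_assoc: bool = True
    run_blocks: bool = True
    run_svcat: bool = True
    run_svgeno: bool = True
    run_tfbs: bool = True
    # thresholds
    max_marker_missing: float = 0.10
    min_maf: float = 0.05
    max_individual_missing: float = 0.10
    snap_min_fail_rate: float = 0.10
    snap_alpha: float = 0.05
    fdr_threshold: float = 0.1
    suggestive_neglog10p: float = 3.0
    min_environments: int = 2
    n_pcs: int = 2
    promoter_bp: int = 10_000
    gabriel: GabrielParams = field(default_factory=GabrielParams)
    tfbs_min_rel_score: float = 0.8

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        design = SimulationDesign(**raw.pop("design", {}))
        gabriel = GabrielParams(**raw.pop("gabriel", {}))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(design=design, gabriel=gabriel, **raw)


def run_pipeline(config: PipelineConfig, outdir: str) -> dict:
    """Execute enabled stages into ``outdir``; returns the manifest dict."""
    os.makedirs(outdir, exist_ok=True)
    config.to_yaml(os.path.join(outdir, "config.yaml"))
    manifest: dict = {"seed": config.seed, "stages": {}}
    state: dict = {}

    stages = [("simulate", _stage_simulate)]
    if config.run_markers:
        stages.append(("markers", _stage_markers))
    if config.run_assoc:
        stages.append(("assoc", _stage_assoc))
    if config.run_blocks:
        stages.append(("ldblocks", _stage_blocks))
    if config.run_assoc:
        stages.append(("qtl", _stage_qtl))
    if config.run_svcat:
        stages.append(("svcat", _stage_svcat))
    if config.run_svgeno:
        stages.append(("svgeno", _stage_svgeno))
    if config.run_tfbs:
        stages.append(("tfbs", _stage_tfbs))

    for name, fn in stages:
        stage_dir = os.path.join(outdir, name)
        os.makedirs(stage_dir, exist_ok=True)
        try:
            manifest["stages"][name] = fn(config, state, stage_dir)
        except Exception as exc:  # halt with a stage-named error
            raise PipelineStageError(name, exc) from exc

    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(config: PipelineConfig, state: dict, outdir: str) -> dict:
    d = config.design
    seed = config.seed
    gmap = GeneticMap.dense(d.chrom_sizes_bp, d.marker_spacing_bp, d.cm_per_mb)
    sv = SVLocusSpec(
        id="SVQ1",
        chrom=d.sv_chrom,
        start=d.sv_start_bp,
        end=d.sv_start_bp + d.sv_size_bp,
        svtype="DEL",
        n_carriers=d.sv_n_carriers,
    )
    founders = simulate_founders(
        d.n_founders, gmap, [sv], seed=seed, block_cm=d.block_cm
    )
    others = [f for f in founders.names if f != founders.common_parent]
    sizes = {f: d.subfamily_size for f in others}
    sizes[others[-1]] = d.short_subfamily_size
    pop = make_dh_population(founders, sizes, seed=seed + 1)
    model = PhenotypeModel(
        grand_mean=d.grand_mean,
        qtl_effects={"SVQ1": d.sv_effect_days},
        var_polygenic=d.var_polygenic,
        var_ge=d.var_ge,
        var_e=d.var_e,
    )
    pheno = simulate_phenotypes(pop, model, n_env=d.n_env, n_reps=d.n_reps, seed=seed + 2)
    svs = founders.sv_records()
    raw_genotypes = inject_call_failures(pop.genotypes, svs, pop.sv_genotypes)
    genes = simulate_genes(
        d.chrom_sizes_bp, d.n_genes_per_chrom, d.flowering_fraction, seed=seed + 3
    )
    # drop the planted SV inside a flowering-annotated gene
    target_gene = None
    for g in genes:
        if g.chrom == sv.chrom and g.start <= sv.start and sv.end <= g.end:
            target_gene = g
            break
    if target_gene is None:
        genes = [g for g in genes if not (g.chrom == sv.chrom and g.start < sv.end and g.end > sv.start)]
        from .svcat import GeneModel

        target_gene = GeneModel(
            id=f"{sv.chrom}gFT",
            chrom=sv.chrom,
            start=max(0, sv.start - 1_000),
            end=sv.end + 2_000,
            strand="+",
            annotation="photoperiodism, flowering, positive regulation of flower development",
        )
        genes.append(target_gene)
        genes.sort(key=lambda g: (g.chrom, g.start))
    else:
        target_gene.annotation = "photoperiodism, flowering, positive regulation of flower development"

    spec = DepthSimSpec(mean_depth=d.mean_depth, dropout_rate=d.dropout_rate)
    geno_class = {
        ind: ("del" if dose == 1 else "ref") for ind, dose in pop.sv_genotypes["SVQ1"].items()
    }
    region = (sv.chrom, max(0, sv.start - 2_000), sv.end + 2_000)
    tracks = simulate_depth(geno_class, (sv.chrom, sv.start, sv.end), region, spec, seed=seed + 4)

    svio.write_map_tsv(gmap, os.path.join(outdir, "map.tsv"), seed)
    svio.write_genotypes_tsv(raw_genotypes, os.path.join(outdir, "genotypes.tsv"), seed)
    svio.write_phenotypes_tsv(pheno, os.path.join(outdir, "phenotypes.tsv"), seed)
    svio.write_sv_vcf(svs, os.path.join(outdir, "sv.vcf"), d.chrom_sizes_bp, seed)
    svio.write_sv_bed(svs, os.path.join(outdir, "sv.bed"), seed)
    svio.write_genes_gff3(genes, os.path.join(outdir, "genes.gff3"), seed)
    first = next(iter(tracks))
    svio.write_depth_bedgraph(tracks[first], os.path.join(outdir, f"depth_{first}.bedgraph"), seed)

    h2 = estimate_heritability(pheno)
    state.update(
        {
            "gmap": gmap,
            "founders": founders,
            "pop": pop,
            "pheno": pheno,
            "svs": svs,
            "sv_spec": sv,
            "raw_genotypes": raw_genotypes,
            "genes": genes,
            "target_gene": target_gene,
            "tracks": tracks,
            "depth_spec": spec,
        }
    )
    return {
        "n_individuals": pop.genotypes.n_individuals,
        "n_markers": pop.genotypes.n_markers,
        "n_sv": len(svs),
        "n_genes": len(genes),
        "h2_estimate": round(h2["h2"], 3),
    }


def _stage_markers(config: PipelineConfig, state: dict, outdir: str) -> dict:
    filtered, report = qc_filter(
        state["raw_genotypes"],
        config.max_marker_missing,
        config.min_maf,
        config.max_individual_missing,
    )
    snaps, recoded = call_snap(
        state["raw_genotypes"], config.snap_min_fail_rate, config.snap_alpha
    )
    report.to_csv(os.path.join(outdir, "qc_exclusions.tsv"), sep="\t", index=False)
    snap_report(snaps).to_csv(os.path.join(outdir, "snap_report.tsv"), sep="\t", index=False)
    state["qc_genotypes"] = filtered
    state["snap_genotypes"] = recoded
    return {
        "n_markers_pass_qc": filtered.n_markers,
        "n_excluded": len(report),
        "n_snap_candidates": len(snaps),
        "n_snap_accepted": sum(s.accepted for s in snaps),
    }


def _combined_matrix(state: dict):
    """QC-passing SNP markers, accepted SNaP recodings and SV presence/absence
    markers, map-ordered."""
    from .genotypes import GenotypeMatrix

    parts = [state["qc_genotypes"]]
    for key in ("snap_genotypes", "sv_marker_genotypes"):
        extra = state.get(key)
        if extra is not None and extra.n_markers:
            parts.append(extra)
    if len(parts) == 1:
        return parts[0]
    g = parts[0]
    calls = np.vstack([p.calls for p in parts])
    markers = pd.concat([p.markers[["chrom", "bp", "cm"]] for p in parts])
    combined = GenotypeMatrix(calls, markers, g.individuals.copy())
    order = np.lexsort((markers["bp"].to_numpy(), markers["chrom"].to_numpy()))
    return combined.select_markers(markers.index[order])


def _stage_assoc(config: PipelineConfig, state: dict, outdir: str) -> dict:
    from .simulate import sv_marker_matrix

    state.setdefault("sv_marker_genotypes", sv_marker_matrix(state["pop"]))
    g = _combined_matrix(state)
    kin = kinship_matrix(state["qc_genotypes"])
    means = entry_means(state["pheno"])
    results = {}
    for env in means.columns:
        res = association_scan(g, means[env], kin, config.n_pcs, environment=env)
        results[env] = res
    all_results = pd.concat(results.values(), ignore_index=True)
    all_results.to_csv(os.path.join(outdir, "associations.tsv"), sep="\t", index=False)
    state["assoc_results"] = results
    n_sig = int((all_results["q"] <= config.fdr_threshold).sum())
    return {"n_tests": len(all_results), "n_significant": n_sig}


def _stage_blocks(config: PipelineConfig, state: dict, outdir: str) -> dict:
    blocks = find_blocks(state["qc_genotypes"], config.gabriel)
    blocks_table(blocks).to_csv(os.path.join(outdir, "blocks.tsv"), sep="\t", index=False)
    state["blocks"] = blocks
    return {"n_blocks": len(blocks)}


def _stage_qtl(config: PipelineConfig, state: dict, outdir: str) -> dict:
    rule = SignificanceRule(
        config.fdr_threshold, config.suggestive_neglog10p, config.min_environments
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        qtls = declare_qtl(state["assoc_results"], rule, state.get("blocks"))
    qtls.to_csv(os.path.join(outdir, "qtl.tsv"), sep="\t", index=False)
    state["qtls"] = qtls
    return {"n_qtl": len(qtls)}


def _stage_svcat(config: PipelineConfig, state: dict, outdir: str) -> dict:
    svs, genes = state["svs"], state["genes"]
    partition = classify_polymorphism(svs)
    sizes = size_classes(partition.polymorphic)
    hits = intersect_genes(svs, genes, config.promoter_bp, strict_chroms=False)
    qtls = state.get("qtls")
    if qtls is None or qtls.empty:
        # user-supplied or fallback intervals: whole-chromosome windows
        qtls = pd.DataFrame(
            [
                {"qtl": f"{c}_all", "chrom": c, "start": 0, "end": size}
                for c, size in config.design.chrom_sizes_bp.items()
            ]
        )
    report = qtl_sv_report(qtls, svs, genes, config.promoter_bp)
    sizes.to_csv(os.path.join(outdir, "size_classes.tsv"), sep="\t")
    hits.to_csv(os.path.join(outdir, "gene_hits.tsv"), sep="\t", index=False)
    report.to_csv(os.path.join(outdir, "qtl_sv_report.tsv"), sep="\t", index=False)
    state["sv_report"] = report
    return {
        "n_polymorphic": len(partition.polymorphic),
        "n_monomorphic": len(partition.monomorphic),
        "n_gene_hits": len(hits),
    }


def _stage_svgeno(config: PipelineConfig, state: dict, outdir: str) -> dict:
    pop, pheno = state["pop"], state["pheno"]
    seg_rows = []
    for sv_id in pop.sv_genotypes.columns:
        for fam, sub in pop.sv_genotypes.groupby(pop.subfamilies):
            counts = sub[sv_id].value_counts()
            if len(counts) < 2:
                continue  # monomorphic subfamily, not tested
            t = segregation_test(int(counts.get(0, 0)), int(counts.get(1, 0)), fam)
            seg_rows.append(
                {
                    "sv": sv_id,
                    "subfamily": fam,
                    "ref": t.count1,
                    "alt": t.count2,
                    "chi2": round(t.chi2, 3),
                    "p": round(t.p, 3),
                    "stars": t.stars,
                }
            )
    seg = pd.DataFrame(seg_rows)

    eff_frames = []
    for sv_id in pop.sv_genotypes.columns:
        eff = allelic_effects(sv_id, pop.sv_genotypes[sv_id], pheno)
        eff_frames.append(effects_table(eff))
    effects = pd.concat(eff_frames, ignore_index=True) if eff_frames else pd.DataFrame()

    sv = state["sv_spec"]
    tracks = state["tracks"]
    calls = {}
    for ind, track in tracks.items():
        calls[ind] = nmc_genotype(
            track, (sv.start, sv.end), individual=ind, baseline_copies=2
        )
    nmc_frame = pd.DataFrame(
        [
            {"individual": ind, "nmc": round(c.nmc, 3), "call": c.call}
            for ind, c in calls.items()
        ]
    )
    truth = {
        ind: ("deletion" if dose == 1 else "reference")
        for ind, dose in state["pop"].sv_genotypes["SVQ1"].items()
    }
    table, agreement = concordance({i: c.call for i, c in calls.items()}, truth)

    seg.to_csv(os.path.join(outdir, "segregation.tsv"), sep="\t", index=False)
    effects.to_csv(os.path.join(outdir, "allelic_effects.tsv"), sep="\t", index=False)
    nmc_frame.to_csv(os.path.join(outdir, "nmc_calls.tsv"), sep="\t", index=False)
    table.to_csv(os.path.join(outdir, "concordance.tsv"), sep="\t")
    state["nmc_calls"] = calls
    return {
        "n_segregation_tests": len(seg),
        "n_effects": len(effects),
        "n_nmc_calls": len(calls),
        "nmc_pcr_agreement": round(float(agreement), 3),
    }


def _stage_tfbs(config: PipelineConfig, state: dict, outdir: str) -> dict:
    sv = state["sv_spec"]
    # deleted sequence with planted circadian-clock binding sites (synthetic;
    # the evening-element-like consensus is used for the demo motif)
    consensus = "AAAATATCT"
    seq = random_sequence(sv.size, seed=config.seed + 5)
    seq = consensus.join([seq[: sv.size // 3], seq[sv.size // 3 : 2 * sv.size // 3]]) + seq[
        2 * sv.size // 3 :
    ]
    seq = seq[: sv.size]
    pfm = make_pfm_from_consensus("EE_like", consensus)
    hits = scan(seq, pfm, config.tfbs_min_rel_score)
    frame = hits_table(hits)
    frame.to_csv(os.path.join(outdir, "motif_hits.tsv"), sep="\t", index=False)
    with open(os.path.join(outdir, "deleted_sequence.fasta"), "w") as fh:
        fh.write(f">{sv.id}_deleted\n{seq}\n")
    return {"n_hits": len(frame), "sequence_length": len(seq)}
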
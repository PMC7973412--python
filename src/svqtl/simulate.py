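"""Synthetic multiparental doubled-haploid (DH) populations.

The generator emulates a nested association mapping design: several inbred
founder lines each crossed to one common elite parent, with each cross
advanced to a subfamily of fully homozygous DH lines (one recombinant F1
gamete, doubled).  Defaults follow the study design this package targets:
7 founders, 6 subfamilies of 60 DH lines (one of 54, 354 in total), 5 field
environments with 2 replicates, and an entry-mean broad-sense heritability
of about 0.83 for days to onset of flowering.

Meiosis uses the Haldane model: crossover counts Poisson with mean equal to
the chromosome map length in Morgans, positions uniform on the cM scale, no
interference.  Founder haplotypes are i.i.d. Bernoulli(0.5) per marker
unless an ancestral-block option is enabled, which plants shared haplotype
blocks of configurable cM length so that linkage-disequilibrium blocks
exist in the population.

Structural-variant loci segregate alongside the markers; deletions can be
projected onto the array genotypes (carrier calls inside a deletion become
"failed", the raw material for SNaP calling) and onto per-base read-depth
tracks (carriers lose coverage inside the deleted interval, the raw
material for normalized-mean-coverage genotyping).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .genotypes import (
    CALL_A,
    CALL_B,
    CALL_FAILED,
    CALL_MISSING,
    GeneticMap,
    GenotypeMatrix,
)
from .svcat import GeneModel, SVRecord

DEFAULT_SUBFAMILY_SIZE = 60
# Study design: six subfamilies of 60 DH lines, except one cross with 54.
SHORT_SUBFAMILY_SIZE = 54


# ---------------------------------------------------------------------------
# founders


@dataclass
class SVLocusSpec:
    """Specification of one simulated SV locus.

    ``carriers`` fixes which founders carry the alternate allele; if omitted
    the generator draws ``n_carriers`` of them (or a random 1..n-1 count) so
    the locus is polymorphic.
    """

    id: str
    chrom: str
    start: int
    end: int
    svtype: str = "DEL"
    size: Optional[int] = None
    carriers: Optional[Sequence[str]] = None
    n_carriers: Optional[int] = None

    def __post_init__(self) -> None:
        if self.svtype == "DEL" and self.size is None:
            self.size = self.end - self.start


@dataclass
class FounderSet:
    """Inbred founder panel: haplotypes at mapped markers plus SV alleles."""

    names: list[str]
    common_parent: str
    gmap: GeneticMap
    haplotypes: dict[str, np.ndarray]  # chrom -> (n_founders, n_markers) 0/1
    sv_loci: list[SVLocusSpec]
    sv_alleles: pd.DataFrame  # founders x sv ids, 0/1

    @property
    def n_founders(self) -> int:
        return len(self.names)

    def haplotype_of(self, founder: str, chrom: str) -> np.ndarray:
        return self.haplotypes[chrom][self.names.index(founder)]

    def sv_records(self) -> list[SVRecord]:
        """Export the SV loci as catalog records with founder alleles."""
        records = []
        for locus in self.sv_loci:
            alleles = {f: int(self.sv_alleles.loc[f, locus.id]) for f in self.names}
            records.append(
                SVRecord(
                    id=locus.id,
                    chrom=locus.chrom,
                    start=locus.start,
                    end=locus.end,
                    svtype=locus.svtype,
                    size=locus.size,
                    founder_alleles=alleles,
                )
            )
        return records


def simulate_founders(
    n_founders: int,
    gmap: GeneticMap,
    sv_loci: Sequence[SVLocusSpec] = (),
    *,
    seed: int,
    common_parent: int = 0,
    block_cm: Optional[float] = None,
    n_ancestral: int = 2,
    names: Optional[Sequence[str]] = None,
) -> FounderSet:
    """Draw fully homozygous founder haplotypes and SV allele assignments.

    With ``block_cm`` set, markers are partitioned into consecutive blocks of
    that genetic length and every founder carries one of ``n_ancestral``
    shared ancestral haplotypes per block — planting LD-block structure.
    Deterministic for a fixed seed.
    """
    if n_founders < 2:
        raise ValueError("need at least two founders")
    rng = np.random.default_rng(seed)
    if names is None:
        names = [f"P{i + 1}" for i in range(n_founders)]
    names = list(names)
    if len(names) != n_founders:
        raise ValueError("names length must equal n_founders")

    haplotypes: dict[str, np.ndarray] = {}
    for chrom in gmap.chromosomes:
        sub = gmap.markers_on(chrom)
        m = len(sub)
        if block_cm is None:
            haplotypes[chrom] = rng.integers(0, 2, size=(n_founders, m), dtype=np.int8)
        else:
            block_idx = (sub["cm"].to_numpy() // block_cm).astype(int)
            n_blocks = block_idx.max() + 1
            ancestral = rng.integers(0, 2, size=(n_ancestral, m), dtype=np.int8)
            choice = rng.integers(0, n_ancestral, size=(n_founders, n_blocks))
            haplotypes[chrom] = ancestral[choice[:, block_idx], np.arange(m)]

    sv_alleles = pd.DataFrame(0, index=names, columns=[s.id for s in sv_loci], dtype=np.int8)
    for locus in sv_loci:
        if locus.chrom not in gmap.chromosomes:
            raise ValueError(f"SV locus {locus.id}: chromosome {locus.chrom!r} not on the map")
        lo, hi = gmap.extent_bp(locus.chrom)
        if not (lo <= locus.start <= hi):
            raise ValueError(
                f"SV locus {locus.id}: position {locus.start} outside map extent "
                f"[{lo}, {hi}] on {locus.chrom}"
            )
        if locus.carriers is not None:
            carriers = list(locus.carriers)
            unknown = set(carriers) - set(names)
            if unknown:
                raise ValueError(f"SV locus {locus.id}: unknown carriers {sorted(unknown)}")
        else:
            k = locus.n_carriers if locus.n_carriers is not None else int(rng.integers(1, n_founders))
            if not 1 <= k <= n_founders - 1:
                raise ValueError(f"SV locus {locus.id}: carrier count {k} not polymorphic")
            carriers = list(rng.choice(names, size=k, replace=False))
        sv_alleles.loc[carriers, locus.id] = 1

    return FounderSet(
        names=names,
        common_parent=names[common_parent],
        gmap=gmap,
        haplotypes=haplotypes,
        sv_loci=list(sv_loci),
        sv_alleles=sv_alleles,
    )


# ---------------------------------------------------------------------------
# DH population


@dataclass
class DHPopulation:
    """A multiparental DH panel: genotype matrix, SV genotypes, pedigree."""

    founders: FounderSet
    genotypes: GenotypeMatrix
    sv_genotypes: pd.DataFrame  # individuals x sv ids, 0/1
    pedigree: pd.DataFrame  # individual -> (common_parent, founder)

    @property
    def individual_ids(self) -> pd.Index:
        return self.genotypes.individual_ids

    @property
    def subfamilies(self) -> pd.Series:
        return self.genotypes.subfamilies


def _gamete_origin(rng: np.random.Generator, length_cm: float, positions_cm: np.ndarray) -> np.ndarray:
    """Parental origin (0 = first parent) at each position of one gamete.

    Haldane model: crossover count Poisson(length in Morgans), positions
    uniform on the cM scale, starting phase fair.
    """
    n_x = rng.poisson(length_cm / 100.0)
    xs = np.sort(rng.uniform(0.0, length_cm, size=n_x))
    phase0 = int(rng.integers(0, 2))
    return (phase0 + np.searchsorted(xs, positions_cm, side="right")) % 2


def make_dh_population(
    founders: FounderSet,
    sizes: Optional[Mapping[str, int]] = None,
    *,
    seed: int,
    viability: Optional[Mapping[str, tuple[int, float]]] = None,
) -> DHPopulation:
    """Generate DH subfamilies, one per non-common founder.

    Each DH line is a single recombinant F1 gamete doubled, hence fully
    homozygous; within a subfamily every locus segregates 1:1 in expectation.
    ``viability`` optionally maps locus id -> (allele, weight<=1): gametes
    carrying that allele survive with the given probability, injecting
    segregation distortion (default off).
    """
    rng = np.random.default_rng(seed)
    others = [f for f in founders.names if f != founders.common_parent]
    if sizes is None:
        sizes = {f: DEFAULT_SUBFAMILY_SIZE for f in others}
        if len(others) == 6:
            sizes[others[-1]] = SHORT_SUBFAMILY_SIZE
    for f, n in sizes.items():
        if n <= 0:
            raise ValueError(f"subfamily size for {f} must be positive")
        if f not in others:
            raise ValueError(f"{f!r} is not a non-common founder")

    gmap = founders.gmap
    chroms = gmap.chromosomes
    marker_pos = {c: gmap.markers_on(c)["cm"].to_numpy() for c in chroms}
    lengths = {c: gmap.length_cm(c) for c in chroms}
    sv_by_chrom: dict[str, list[tuple[int, SVLocusSpec]]] = {c: [] for c in chroms}
    for k, locus in enumerate(founders.sv_loci):
        sv_by_chrom[locus.chrom].append((k, locus))
    sv_pos = {
        c: np.array([gmap.interpolate_cm(c, loc.start) for _, loc in sv_by_chrom[c]])
        for c in chroms
    }
    common_idx = founders.names.index(founders.common_parent)
    n_sv = len(founders.sv_loci)
    viability = dict(viability or {})

    ind_ids, subfam, calls_cols, sv_rows = [], [], [], []
    for f in others:
        f_idx = founders.names.index(f)
        for i in range(sizes[f]):
            for _attempt in range(1000):
                marker_calls = []
                sv_calls = np.zeros(n_sv, dtype=np.int8)
                for c in chroms:
                    pos = np.concatenate([marker_pos[c], sv_pos[c]])
                    origin = _gamete_origin(rng, lengths[c], pos)
                    m = len(marker_pos[c])
                    parent_rows = np.where(origin[:m] == 0, common_idx, f_idx)
                    marker_calls.append(
                        founders.haplotypes[c][parent_rows, np.arange(m)]
                    )
                    for j, (k, locus) in enumerate(sv_by_chrom[c]):
                        parent = founders.common_parent if origin[m + j] == 0 else f
                        sv_calls[k] = founders.sv_alleles.loc[parent, locus.id]
                genotype = np.concatenate(marker_calls)
                if _survives(rng, genotype, sv_calls, founders, viability):
                    break
            ind_ids.append(f"{f}_DH{i + 1:03d}")
            subfam.append(f)
            calls_cols.append(genotype)
            sv_rows.append(sv_calls)

    calls = np.column_stack(calls_cols).astype(np.int8)
    markers = gmap.table.copy()
    individuals = pd.DataFrame({"subfamily": subfam}, index=pd.Index(ind_ids, name="individual"))
    genotypes = GenotypeMatrix(calls, markers, individuals)
    sv_genotypes = pd.DataFrame(
        np.array(sv_rows, dtype=np.int8).reshape(len(ind_ids), n_sv),
        index=individuals.index,
        columns=[s.id for s in founders.sv_loci],
    )
    pedigree = pd.DataFrame(
        {"mother": founders.common_parent, "father": subfam}, index=individuals.index
    )
    return DHPopulation(founders, genotypes, sv_genotypes, pedigree)


def sv_marker_matrix(pop: DHPopulation) -> GenotypeMatrix:
    """SV presence/absence genotypes as biallelic markers (A = reference).

    Mirrors adding a locus-specific assay's calls to an association scan
    alongside the array markers.
    """
    loci = pop.founders.sv_loci
    calls = pop.sv_genotypes.to_numpy(dtype=np.int8).T
    markers = pd.DataFrame(
        {
            "chrom": [s.chrom for s in loci],
            "bp": [s.start for s in loci],
            "cm": [
                float(pop.founders.gmap.interpolate_cm(s.chrom, s.start)) for s in loci
            ],
        },
        index=pd.Index([s.id for s in loci], name="marker"),
    )
    return GenotypeMatrix(calls, markers, pop.genotypes.individuals.copy())


def _survives(rng, genotype, sv_calls, founders, viability) -> bool:
    if not viability:
        return True
    marker_index = founders.gmap.table.index
    sv_ids = [s.id for s in founders.sv_loci]
    p = 1.0
    for locus_id, (allele, weight) in viability.items():
        if locus_id in sv_ids:
            value = sv_calls[sv_ids.index(locus_id)]
        else:
            value = genotype[marker_index.get_loc(locus_id)]
        if value == allele:
            p *= weight
    return p >= 1.0 or rng.uniform() < p


# ---------------------------------------------------------------------------
# phenotypes


@dataclass
class PhenotypeModel:
    """Linear model for days to onset of flowering (BBCH 61).

    phenotype = grand_mean + environment effect + sum(QTL effect x dose)
              + polygenic value + GxE draw + residual.

    Doses are 0/1 (homozygous DH lines; a QTL effect is the difference
    between the two genotype-class means, in days).  ``var_polygenic`` adds
    an i.i.d. normal genetic value per line, used to set genotypic variance
    directly when no individual QTL are modelled.  All variances in days^2.
    """

    grand_mean: float = 245.0
    env_effects: Optional[Sequence[float]] = None
    var_env: float = 4.0
    qtl_effects: Mapping[str, float] = field(default_factory=dict)
    var_polygenic: float = 0.0
    var_ge: float = 0.0
    var_e: float = 1.0

    def __post_init__(self) -> None:
        for name in ("var_env", "var_polygenic", "var_ge", "var_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def heritability_expected(var_g: float, var_ge: float, var_e: float, n_env: int, n_reps: int) -> float:
    """Closed-form entry-mean broad-sense heritability
    H2 = s2G / (s2G + s2GE/E + s2e/(E*R))."""
    return var_g / (var_g + var_ge / n_env + var_e / (n_env * n_reps))


def simulate_phenotypes(
    pop: DHPopulation,
    model: PhenotypeModel,
    *,
    n_env: int = 5,
    n_reps: int = 2,
    seed: int,
) -> pd.DataFrame:
    """Long-format phenotype table (individual, environment, replicate, days)."""
    rng = np.random.default_rng(seed)
    inds = pop.individual_ids
    n = len(inds)

    genetic = np.zeros(n)
    for locus, effect in model.qtl_effects.items():
        if locus in pop.sv_genotypes.columns:
            dose = pop.sv_genotypes[locus].to_numpy(dtype=float)
        elif locus in pop.genotypes.marker_ids:
            row = pop.genotypes.calls[pop.genotypes.marker_ids.get_loc(locus)]
            if (row < 0).any():
                raise ValueError(f"QTL locus {locus} has ungenotyped individuals")
            dose = (row == CALL_B).astype(float)
        else:
            raise KeyError(f"QTL locus {locus!r} not genotyped in the population")
        genetic = genetic + effect * dose
    if model.var_polygenic > 0:
        genetic = genetic + rng.normal(0.0, np.sqrt(model.var_polygenic), size=n)

    if model.env_effects is not None:
        env_eff = np.asarray(model.env_effects, dtype=float)
        if len(env_eff) != n_env:
            raise ValueError("env_effects length must equal n_env")
    else:
        env_eff = rng.normal(0.0, np.sqrt(model.var_env), size=n_env)

    ge = rng.normal(0.0, np.sqrt(model.var_ge), size=(n, n_env)) if model.var_ge > 0 else np.zeros((n, n_env))
    rows = []
    for j in range(n_env):
        for r in range(n_reps):
            resid = rng.normal(0.0, np.sqrt(model.var_e), size=n) if model.var_e > 0 else np.zeros(n)
            days = model.grand_mean + env_eff[j] + genetic + ge[:, j] + resid
            rows.append(
                pd.DataFrame(
                    {
                        "individual": inds,
                        "environment": f"E{j + 1}",
                        "replicate": r + 1,
                        "days": days,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def entry_means(pheno: pd.DataFrame) -> pd.DataFrame:
    """Per-individual, per-environment means over replicates (wide frame)."""
    return pheno.pivot_table(index="individual", columns="environment", values="days", aggfunc="mean")


def estimate_heritability(pheno: pd.DataFrame) -> dict:
    """Entry-mean broad-sense heritability from balanced two-way ANOVA.

    Expected mean squares for a genotype x environment design with R
    replicates give s2e = MS_error, s2GE = (MS_GE - MS_error)/R and
    s2G = (MS_G - MS_GE)/(E*R); negative component estimates are clipped
    at zero.  Requires a balanced table with R >= 2.
    """
    counts = pheno.groupby(["individual", "environment"])["days"].count()
    if counts.nunique() != 1:
        raise ValueError("phenotype table must be balanced")
    n_reps = int(counts.iloc[0])
    if n_reps < 2:
        raise ValueError("need at least two replicates to separate error from GxE")
    cell = pheno.pivot_table(index="individual", columns="environment", values="days", aggfunc="mean")
    y = pheno.pivot_table(index="individual", columns=["environment", "replicate"], values="days")
    n_g, n_env = cell.shape
    grand = float(cell.to_numpy().mean())
    gm = cell.mean(axis=1).to_numpy()
    em = cell.mean(axis=0).to_numpy()

    ss_g = n_env * n_reps * float(((gm - grand) ** 2).sum())
    ss_ge = n_reps * float(
        ((cell.to_numpy() - gm[:, None] - em[None, :] + grand) ** 2).sum()
    )
    resid = y.to_numpy().reshape(n_g, n_env, n_reps) - cell.to_numpy()[:, :, None]
    ss_err = float((resid**2).sum())

    ms_g = ss_g / (n_g - 1)
    ms_ge = ss_ge / ((n_g - 1) * (n_env - 1))
    ms_err = ss_err / (n_g * n_env * (n_reps - 1))
    var_e = ms_err
    var_ge = max((ms_ge - ms_err) / n_reps, 0.0)
    var_g = max((ms_g - ms_ge) / (n_env * n_reps), 0.0)
    h2 = heritability_expected(var_g, var_ge, var_e, n_env, n_reps)
    return {"h2": h2, "var_g": var_g, "var_ge": var_ge, "var_e": var_e}


# ---------------------------------------------------------------------------
# depth tracks and call failures


@dataclass
class DepthSimSpec:
    """Read-depth model for deletion genotyping.

    Homozygous deletion carriers retain ``dropout_rate`` of baseline depth
    inside the deleted interval (residual mis-mapping), heterozygotes half,
    reference individuals full depth.
    """

    mean_depth: float = 30.0
    dropout_rate: float = 0.05

    def __post_init__(self) -> None:
        if not 0 <= self.dropout_rate < 0.5:
            raise ValueError("dropout_rate must be in [0, 0.5)")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")

    def dosage(self, genotype: str) -> float:
        return {"ref": 1.0, "het": 0.5, "del": self.dropout_rate}[genotype]


@dataclass
class DepthTrack:
    """Per-base integer coverage over one reference window."""

    chrom: str
    start: int  # 0-based
    depth: np.ndarray

    @property
    def end(self) -> int:
        return self.start + len(self.depth)

    def mean_over(self, start: int, end: int) -> float:
        s = max(start, self.start) - self.start
        e = min(end, self.end) - self.start
        if e <= s:
            raise ValueError("interval does not overlap the track")
        return float(self.depth[s:e].mean())


def simulate_depth(
    genotypes: Mapping[str, str],
    sv_interval: tuple[str, int, int],
    region: tuple[str, int, int],
    spec: DepthSimSpec = DepthSimSpec(),
    *,
    seed: int,
) -> dict[str, DepthTrack]:
    """Poisson per-base depth tracks for a panel at one deletion locus.

    ``genotypes`` maps individual -> {"ref", "het", "del"}.  Depth is
    Poisson(mean_depth x dosage) inside the deleted interval and
    Poisson(mean_depth) elsewhere in ``region``.
    """
    chrom, rs, re_ = region
    sv_chrom, ss, se = sv_interval
    if sv_chrom != chrom or not (rs <= ss < se <= re_):
        raise ValueError("SV interval must lie within the simulated region")
    rng = np.random.default_rng(seed)
    tracks = {}
    length = re_ - rs
    inside = np.zeros(length, dtype=bool)
    inside[ss - rs : se - rs] = True
    for ind, geno in genotypes.items():
        mean = np.where(inside, spec.mean_depth * spec.dosage(geno), spec.mean_depth)
        tracks[ind] = DepthTrack(chrom, rs, rng.poisson(mean).astype(np.int32))
    return tracks


def inject_call_failures(
    g: GenotypeMatrix, svs: Sequence[SVRecord], sv_genotypes: pd.DataFrame
) -> GenotypeMatrix:
    """Fail array calls at markers physically inside a deletion, in carriers.

    Emulates probe dropout on a genotyping array: a deleted probe site gives
    a systematically failed call in every individual carrying the deletion.
    Non-carriers and markers outside all deletions are untouched.
    """
    out = g.copy()
    bp = g.markers["bp"].to_numpy()
    chrom = g.markers["chrom"].to_numpy()
    for sv in svs:
        if sv.svtype != "DEL":
            continue
        in_del = (chrom == sv.chrom) & (bp >= sv.start) & (bp < sv.end)
        if not in_del.any():
            continue
        carriers = sv_genotypes[sv.id].to_numpy() == 1
        cols = g.individual_ids.get_indexer(sv_genotypes.index[carriers])
        out.calls[np.ix_(np.flatnonzero(in_del), cols)] = CALL_FAILED
    return out


# ---------------------------------------------------------------------------
# annotation and sequence


_FLOWERING_ANNOTATIONS = (
    "regulation of flower development",
    "photoperiodism, flowering",
    "entrainment of circadian clock",
    "vernalization response",
    "floral organ development",
    "circadian rhythm",
    "pollen development",
    "vegetative to reproductive phase transition",
)

_NEUTRAL_ANNOTATIONS = (
    "ATP binding",
    "protein kinase activity",
    "DNA repair",
    "lipid metabolic process",
    "transmembrane transport",
    "ribosome biogenesis",
    "oxidation-reduction process",
    "cell wall organization",
)


def simulate_genes(
    chrom_sizes_bp: Mapping[str, int],
    n_genes_per_chrom: int = 50,
    flowering_fraction: float = 0.1,
    *,
    seed: int,
    gene_length_bp: tuple[int, int] = (2_000, 6_000),
) -> list[GeneModel]:
    """Non-overlapping gene models with free-text functional annotations.

    A configurable fraction receives a flowering-related annotation drawn
    from a small phrase pool; the rest get neutral housekeeping terms.
    """
    rng = np.random.default_rng(seed)
    genes = []
    for chrom, size in chrom_sizes_bp.items():
        slots = np.sort(rng.choice(np.arange(1, size - gene_length_bp[1], 1000), size=n_genes_per_chrom, replace=False))
        prev_end = 0
        for i, s in enumerate(slots):
            start = max(int(s), prev_end + 1)
            length = int(rng.integers(*gene_length_bp))
            end = min(start + length, size)
            if end <= start:
                continue
            prev_end = end
            flowering = rng.uniform() < flowering_fraction
            pool = _FLOWERING_ANNOTATIONS if flowering else _NEUTRAL_ANNOTATIONS
            genes.append(
                GeneModel(
                    id=f"{chrom}g{i + 1:04d}",
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand="+" if rng.uniform() < 0.5 else "-",
                    annotation=str(rng.choice(pool)),
                )
            )
    return genes


def random_sequence(length: int, *, seed: int, gc: float = 0.4) -> str:
    """Random nucleotide sequence with the given GC content."""
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list("ACGT"), size=length, p=p))
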
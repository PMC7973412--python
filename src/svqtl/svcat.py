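"""Structural-variant catalog handling.

Deletions and insertions (>= 30 bp, the practical lower bound for long-read
discovery) are classified as polymorphic or monomorphic across the founder
panel, binned into size classes, and intersected with gene bodies and
promoter windows.  A keyword filter over free-text functional annotations
flags flowering-time candidate genes, and a per-QTL report summarizes
SV-bearing candidate genes inside QTL intervals.

All coordinates are 0-based half-open internally; converters at the I/O
boundary handle 1-based formats (VCF, GFF3).
"""

from __future__ import annotations

import warnings
from collections import namedtuple
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

MIN_SV_SIZE = 30

#: Default keyword set for flagging flowering-time candidate genes in
#: free-text GO/Blast2GO annotation ("pollen" and "carpel" as separate terms).
FLOWERING_KEYWORDS = (
    "flower",
    "vernalization",
    "photoperiod",
    "circadian",
    "floral",
    "vegetative to reproductive",
    "vegetative phase change",
    "pollen",
    "carpel",
    "sepal",
    "petal",
)

SIZE_CLASS_LABELS = ("30-99", "100-999", "1000-9999", ">=10000")
_SIZE_CLASS_EDGES = (30, 100, 1_000, 10_000)


@dataclass
class SVRecord:
    """A deletion or insertion call with per-founder alleles.

    For deletions ``[start, end)`` is the deleted reference span and
    ``size == end - start``.  Insertions are anchored at ``start`` (the
    reference breakpoint); ``size`` is the inserted length.  Founder alleles
    are coded 0 (reference), 1 (alternate) or ``None`` (unknown).
    """

    id: str
    chrom: str
    start: int
    end: int
    svtype: str
    size: Optional[int] = None
    founder_alleles: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.svtype not in ("DEL", "INS"):
            raise ValueError(f"{self.id}: svtype must be DEL or INS, got {self.svtype!r}")
        if self.svtype == "DEL":
            if self.end <= self.start:
                raise ValueError(f"{self.id}: deletion needs end > start")
            inferred = self.end - self.start
            if self.size is None:
                self.size = inferred
            elif self.size != inferred:
                raise ValueError(f"{self.id}: DEL size {self.size} != end-start {inferred}")
        else:
            if self.size is None:
                raise ValueError(f"{self.id}: insertion needs an explicit size")
        if self.size < MIN_SV_SIZE:
            raise ValueError(f"{self.id}: size {self.size} below minimum {MIN_SV_SIZE} bp")

    def interval(self) -> tuple[int, int]:
        """Reference footprint used for interval arithmetic (INS = 1 bp anchor)."""
        if self.svtype == "DEL":
            return self.start, self.end
        return self.start, self.start + 1


@dataclass
class GeneModel:
    """A gene with coordinates, strand and free-text functional annotation."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    annotation: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.id}: gene needs start < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.id}: strand must be '+' or '-'")


PolymorphismPartition = namedtuple("PolymorphismPartition", "polymorphic monomorphic unknown")


def classify_polymorphism(svs: Sequence[SVRecord]) -> PolymorphismPartition:
    """Partition SV calls into polymorphic vs monomorphic across founders.

    Monomorphic means all *known* founder alleles are identical — including
    the all-alternate case, a shared difference from the reference assembly.
    Records whose founder alleles are all unknown are returned separately.
    """
    polymorphic, monomorphic, unknown = [], [], []
    for sv in svs:
        alleles = {a for a in sv.founder_alleles.values() if a is not None}
        if not alleles:
            unknown.append(sv)
        elif len(alleles) == 1:
            monomorphic.append(sv)
        else:
            polymorphic.append(sv)
    return PolymorphismPartition(polymorphic, monomorphic, unknown)


def size_class(size: int) -> str:
    """Size-class label with half-open, lower-inclusive bins."""
    if size < MIN_SV_SIZE:
        raise ValueError(f"size {size} below minimum {MIN_SV_SIZE} bp")
    idx = int(np.searchsorted(_SIZE_CLASS_EDGES, size, side="right")) - 1
    return SIZE_CLASS_LABELS[idx]


def size_classes(svs: Sequence[SVRecord]) -> pd.DataFrame:
    """Counts of SV per size class and type (rows sum to the total)."""
    table = pd.DataFrame(
        0, index=list(SIZE_CLASS_LABELS), columns=["DEL", "INS", "total"], dtype=int
    )
    for sv in svs:
        label = size_class(sv.size)
        table.loc[label, sv.svtype] += 1
        table.loc[label, "total"] += 1
    return table


def _promoter_window(gene: GeneModel, promoter_bp: int) -> tuple[int, int]:
    # Anchored at the gene start (approximation of "upstream of the start codon").
    if gene.strand == "+":
        return max(0, gene.start - promoter_bp), gene.start
    return gene.end, gene.end + promoter_bp


def intersect_genes(
    svs: Sequence[SVRecord],
    genes: Sequence[GeneModel],
    promoter_bp: int = 10_000,
    strict_chroms: bool = True,
) -> pd.DataFrame:
    """Intersect SV footprints with gene bodies and upstream promoter windows.

    Returns a frame with one row per (sv, gene, relation) hit, relation in
    ``{"intragenic", "promoter"}``.  Half-open interval arithmetic throughout;
    an SV may hit several genes, and a gene may be hit both intragenically
    and in its promoter by different SV.
    """
    gene_chroms = {g.chrom for g in genes}
    if strict_chroms:
        bad = [sv.id for sv in svs if sv.chrom not in gene_chroms]
        if bad:
            raise ValueError(f"SV records on chromosomes absent from the annotation: {bad}")

    body_trees: dict[str, IntervalTree] = {}
    prom_trees: dict[str, IntervalTree] = {}
    for g in genes:
        body_trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g)
        ps, pe = _promoter_window(g, promoter_bp)
        if pe > ps:
            prom_trees.setdefault(g.chrom, IntervalTree()).addi(ps, pe, g)

    rows = []
    for sv in svs:
        s, e = sv.interval()
        for iv in sorted(body_trees.get(sv.chrom, IntervalTree()).overlap(s, e)):
            rows.append({"sv": sv.id, "gene": iv.data.id, "relation": "intragenic"})
        for iv in sorted(prom_trees.get(sv.chrom, IntervalTree()).overlap(s, e)):
            rows.append({"sv": sv.id, "gene": iv.data.id, "relation": "promoter"})
    return pd.DataFrame(rows, columns=["sv", "gene", "relation"])


def flowering_filter(
    genes: Sequence[GeneModel], keywords: Sequence[str] = FLOWERING_KEYWORDS
) -> list[GeneModel]:
    """Genes whose annotation contains any keyword (case-insensitive substring)."""
    lowered = [k.lower() for k in keywords]
    return [g for g in genes if any(k in g.annotation.lower() for k in lowered)]


def qtl_sv_report(
    qtls: pd.DataFrame,
    svs: Sequence[SVRecord],
    genes: Sequence[GeneModel],
    promoter_bp: int = 10_000,
    keywords: Sequence[str] = FLOWERING_KEYWORDS,
) -> pd.DataFrame:
    """Per-QTL summary of genes, flowering-time candidates and coinciding SV.

    ``qtls`` needs columns ``qtl``, ``chrom``, ``start``, ``end`` (0-based
    half-open).  Each output row counts genes inside the QTL interval, the
    flowering-flagged subset, how many of each carry SV (intragenic or
    promoter), and lists the SV-bearing flowering genes with their SV.
    """
    hits = intersect_genes(svs, genes, promoter_bp=promoter_bp, strict_chroms=False)
    sv_by_id = {sv.id: sv for sv in svs}
    flowering_ids = {g.id for g in flowering_filter(genes, keywords)}
    sv_genes = set(hits["gene"]) if not hits.empty else set()

    rows = []
    for q in qtls.itertuples(index=False):
        in_qtl = [g for g in genes if g.chrom == q.chrom and g.start < q.end and g.end > q.start]
        ids = {g.id for g in in_qtl}
        flower = ids & flowering_ids
        with_sv = ids & sv_genes
        flower_sv = sorted(flower & sv_genes)
        descriptions = []
        for gid in flower_sv:
            for _, h in hits[hits["gene"] == gid].iterrows():
                sv = sv_by_id[h["sv"]]
                descriptions.append(f"{sv.id}: {sv.size} bp {sv.svtype} ({h['relation']})")
        rows.append(
            {
                "qtl": q.qtl,
                "chrom": q.chrom,
                "start": q.start,
                "end": q.end,
                "size_kb": (q.end - q.start) / 1000.0,
                "n_genes": len(ids),
                "n_flowering": len(flower),
                "pct_flowering": round(100.0 * len(flower) / len(ids), 1) if ids else 0.0,
                "n_genes_with_sv": len(with_sv),
                "pct_genes_with_sv": round(100.0 * len(with_sv) / len(ids), 1) if ids else 0.0,
                "n_flowering_with_sv": len(flower_sv),
                "flowering_sv_genes": ";".join(flower_sv) if flower_sv else "-",
                "sv_details": ";".join(descriptions) if descriptions else "-",
            }
        )
    return pd.DataFrame(rows)
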
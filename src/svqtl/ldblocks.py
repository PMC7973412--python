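"""Linkage-disequilibrium blocks by the D' confidence-interval method.

Pairwise disequilibrium between biallelic loci is summarized by the
normalized coefficient D' = D / Dmax, with a likelihood-based confidence
interval on |D'| computed over a grid (the Wall-Pritchard approach used by
Haploview).  Pairs are classified as "strong LD", "strong recombination" or
"uninformative" from the CI bounds, and blocks are maximal marker spans in
which at least 95% of informative pairs are in strong LD.  Parameter
defaults are the Haploview defaults (90% CI, 0.70/0.98 strong-LD bounds,
0.90 recombination bound).

Fully homozygous lines expose their haplotypes directly, so haplotype
counts are read off the genotype matrix without phasing; a two-locus EM is
provided for heterozygous input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genotypes import CALL_A, CALL_B, GenotypeMatrix

STRONG_LD = "strong LD"
STRONG_RECOMB = "strong recombination"
UNINFORMATIVE = "uninformative"


@dataclass
class GabrielParams:
    """Classification thresholds for D'-CI block finding (Haploview defaults)."""

    ci_level: float = 0.90
    strong_ci_low: float = 0.70
    strong_ci_high: float = 0.98
    recomb_ci_high: float = 0.90
    strong_fraction: float = 0.95
    grid_step: float = 0.001


@dataclass
class PairLD:
    """Pairwise disequilibrium summary for two biallelic loci."""

    d: float
    dprime: float
    ci_low: float
    ci_high: float
    classification: str


@dataclass
class LDBlock:
    """A chromosome interval of contiguous markers in strong pairwise LD."""

    chrom: str
    start: int
    end: int
    markers: list[str]

    @property
    def size_kb(self) -> float:
        return (self.end - self.start) / 1000.0


def haplotype_counts(g: GenotypeMatrix, marker_i: str, marker_j: str) -> tuple[int, int, int, int]:
    """Two-locus haplotype counts (AB, Ab, aB, ab) from homozygous lines.

    A/a are the CALL_A/CALL_B alleles at the first locus, B/b at the second.
    Individuals missing either call are dropped.
    """
    ri = g.calls[g.marker_ids.get_loc(marker_i)]
    rj = g.calls[g.marker_ids.get_loc(marker_j)]
    ok = (ri >= 0) & (rj >= 0)
    ri, rj = ri[ok], rj[ok]
    return (
        int(((ri == CALL_A) & (rj == CALL_A)).sum()),
        int(((ri == CALL_A) & (rj == CALL_B)).sum()),
        int(((ri == CALL_B) & (rj == CALL_A)).sum()),
        int(((ri == CALL_B) & (rj == CALL_B)).sum()),
    )


def pair_ld(counts: Sequence[int], params: GabrielParams = GabrielParams()) -> PairLD:
    """D, D' and a likelihood-grid confidence interval on |D'|.

    ``counts`` are haplotype counts (AB, Ab, aB, ab).  A monomorphic locus
    yields the "uninformative" classification rather than an error.
    """
    counts = np.asarray(counts, dtype=float)  # AB, Ab, aB, ab
    n = counts.sum()
    if n == 0:
        return PairLD(np.nan, np.nan, np.nan, np.nan, UNINFORMATIVE)
    p_ab = counts[0] / n
    p_a = (counts[0] + counts[1]) / n  # freq of allele A at locus 1
    p_b = (counts[0] + counts[2]) / n  # freq of allele B at locus 2
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        return PairLD(np.nan, np.nan, np.nan, np.nan, UNINFORMATIVE)

    d = p_ab - p_a * p_b
    if d >= 0:
        dmax = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        dmax = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    dprime = d / dmax if dmax > 0 else 0.0

    # Likelihood of |D'| on a grid, holding allele frequencies and the sign
    # of D at their observed values.
    grid = np.arange(0.0, 1.0 + params.grid_step / 2, params.grid_step)
    sign = 1.0 if d >= 0 else -1.0
    dd = sign * grid * dmax
    p11 = np.clip(p_a * p_b + dd, 1e-12, 1.0)
    p12 = np.clip(p_a * (1 - p_b) - dd, 1e-12, 1.0)
    p21 = np.clip((1 - p_a) * p_b - dd, 1e-12, 1.0)
    p22 = np.clip((1 - p_a) * (1 - p_b) + dd, 1e-12, 1.0)
    loglik = (
        counts[0] * np.log(p11)
        + counts[1] * np.log(p12)
        + counts[2] * np.log(p21)
        + counts[3] * np.log(p22)
    )
    lik = np.exp(loglik - loglik.max())
    cdf = np.cumsum(lik)
    cdf /= cdf[-1]
    tail = (1.0 - params.ci_level) / 2.0
    ci_low = float(grid[int(np.searchsorted(cdf, tail))])
    ci_high = float(grid[min(int(np.searchsorted(cdf, 1.0 - tail)), len(grid) - 1)])

    if ci_low >= params.strong_ci_low and ci_high >= params.strong_ci_high:
        classification = STRONG_LD
    elif ci_high < params.recomb_ci_high:
        classification = STRONG_RECOMB
    else:
        classification = UNINFORMATIVE
    return PairLD(float(d), float(abs(dprime)), ci_low, ci_high, classification)


def em_haplotype_counts(genotype_table: np.ndarray, n_iter: int = 100) -> np.ndarray:
    """Expected haplotype counts from unphased diploid two-locus genotypes.

    ``genotype_table`` is the 3x3 table of joint genotype counts (rows: 0/1/2
    copies of allele a at locus 1; columns: same for locus 2).  Standard EM
    over the double-heterozygote phase ambiguity.
    """
    t = np.asarray(genotype_table, dtype=float)
    if t.shape != (3, 3):
        raise ValueError("genotype table must be 3x3")
    freqs = np.full(4, 0.25)  # AB, Ab, aB, ab
    for _ in range(n_iter):
        h = np.zeros(4)
        h[0] = 2 * t[0, 0] + t[0, 1] + t[1, 0]
        h[1] = 2 * t[0, 2] + t[0, 1] + t[1, 2]
        h[2] = 2 * t[2, 0] + t[1, 0] + t[2, 1]
        h[3] = 2 * t[2, 2] + t[2, 1] + t[1, 2]
        cis = freqs[0] * freqs[3]
        trans = freqs[1] * freqs[2]
        total = cis + trans
        frac = 0.5 if total == 0 else cis / total
        h[0] += t[1, 1] * frac
        h[3] += t[1, 1] * frac
        h[1] += t[1, 1] * (1 - frac)
        h[2] += t[1, 1] * (1 - frac)
        freqs = h / h.sum()
    return freqs * 2 * t.sum()


def pairwise_ld(
    g: GenotypeMatrix, chrom: str, params: GabrielParams = GabrielParams(), max_span_markers: int = 50
) -> pd.DataFrame:
    """PairLD for all within-window marker pairs on one chromosome, map order."""
    sub = g.select_markers(np.asarray(g.markers["chrom"] == chrom))
    ids = list(sub.marker_ids)
    rows = []
    for i in range(len(ids)):
        for j in range(i + 1, min(i + 1 + max_span_markers, len(ids))):
            pl = pair_ld(haplotype_counts(sub, ids[i], ids[j]), params)
            rows.append(
                {
                    "marker_i": ids[i],
                    "marker_j": ids[j],
                    "i": i,
                    "j": j,
                    "d": pl.d,
                    "dprime": pl.dprime,
                    "ci_low": pl.ci_low,
                    "ci_high": pl.ci_high,
                    "classification": pl.classification,
                }
            )
    return pd.DataFrame(rows)


def find_blocks(
    g: GenotypeMatrix,
    params: GabrielParams = GabrielParams(),
    max_span_markers: int = 50,
) -> list[LDBlock]:
    """Maximal non-overlapping strong-LD spans over all chromosomes.

    A candidate span is a block when it has at least one informative pair,
    at least one strong-LD pair, and the strong-LD fraction among
    informative pairs is at least ``strong_fraction``.  Candidates are
    resolved longest-first (physical span, then marker count) into
    non-overlapping blocks of two or more markers.
    """
    blocks: list[LDBlock] = []
    for chrom in dict.fromkeys(g.markers["chrom"]):
        sub = g.select_markers(np.asarray(g.markers["chrom"] == chrom))
        m = sub.n_markers
        if m < 2:
            continue
        pairs = pairwise_ld(g, chrom, params, max_span_markers)
        strong = np.zeros((m, m), dtype=np.int64)
        informative = np.zeros((m, m), dtype=np.int64)
        for row in pairs.itertuples(index=False):
            if row.classification == STRONG_LD:
                strong[row.i, row.j] = strong[row.j, row.i] = 1
                informative[row.i, row.j] = informative[row.j, row.i] = 1
            elif row.classification == STRONG_RECOMB:
                informative[row.i, row.j] = informative[row.j, row.i] = 1
        strong_ps = strong.cumsum(axis=0).cumsum(axis=1)
        info_ps = informative.cumsum(axis=0).cumsum(axis=1)

        def _square_sum(ps: np.ndarray, i: int, j: int) -> int:
            total = ps[j, j]
            if i > 0:
                total -= ps[i - 1, j] + ps[j, i - 1] - ps[i - 1, i - 1]
            return int(total) // 2  # symmetric, zero diagonal

        bp = sub.markers["bp"].to_numpy()
        candidates = []
        for i in range(m):
            for j in range(i + 1, min(i + 1 + max_span_markers, m)):
                n_info = _square_sum(info_ps, i, j)
                n_strong = _square_sum(strong_ps, i, j)
                if n_info == 0 or n_strong == 0:
                    continue
                if n_strong / n_info >= params.strong_fraction:
                    candidates.append((int(bp[j] - bp[i]), j - i, i, j))
        candidates.sort(key=lambda c: (-c[0], -c[1], c[2]))
        taken = np.zeros(m, dtype=bool)
        for _, _, i, j in candidates:
            if taken[i : j + 1].any():
                continue
            taken[i : j + 1] = True
            blocks.append(
                LDBlock(
                    chrom=chrom,
                    start=int(bp[i]),
                    end=int(bp[j]),
                    markers=list(sub.marker_ids[i : j + 1]),
                )
            )
    blocks.sort(key=lambda b: (b.chrom, b.start))
    return blocks


def blocks_table(blocks: Sequence[LDBlock]) -> pd.DataFrame:
    """1-based-inclusive summary table of blocks with sizes in kb."""
    return pd.DataFrame(
        [
            {
                "chrom": b.chrom,
                "start": b.start,
                "end": b.end,
                "size_kb": b.size_kb,
                "n_markers": len(b.markers),
                "markers": ",".join(b.markers),
            }
            for b in blocks
        ],
        columns=["chrom", "start", "end", "size_kb", "n_markers", "markers"],
    )


def blocks_to_bed(blocks: Sequence[LDBlock]) -> pd.DataFrame:
    """0-based half-open BED frame (chrom, start, end, name)."""
    return pd.DataFrame(
        [
            {"chrom": b.chrom, "start": b.start - 1, "end": b.end, "name": f"block_{k + 1}"}
            for k, b in enumerate(blocks)
        ],
        columns=["chrom", "start", "end", "name"],
    )
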
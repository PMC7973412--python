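"""Locus-specific SV genotyping and effect testing.

Four independent lines of evidence about a single deletion/insertion locus:

* in-silico PCR: predicted product sizes per allele from primer footprints
  (a deletion strictly between the primers shortens the product by its size;
  an insertion lengthens it; an SV disrupting a primer site gives no product),
* chi-square segregation tests against the 1:1 ratio expected in a DH
  subfamily,
* per-environment allelic effects on days to flowering with two-sided
  pooled-variance Student's t tests,
* normalized mean coverage (NMC) deletion genotyping from read depth:
  NMC < 0.5 calls a homozygous deletion, NMC > 1.5 the reference, anything
  between is ambiguous (heterozygotes sit near 0.5-1.5 by construction and
  are not callable from coverage alone).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import DepthTrack
from .svcat import SVRecord

NMC_DELETION_BELOW = 0.5
NMC_REFERENCE_ABOVE = 1.5

NO_PRODUCT = "no product"


@dataclass
class PCRAssay:
    """A locus-specific PCR assay defined by its two primer footprints.

    Footprints are 0-based half-open reference intervals; the reference
    amplicon spans from the start of the left footprint to the end of the
    right one.
    """

    id: str
    chrom: str
    primer1: tuple[int, int]
    primer2: tuple[int, int]

    def __post_init__(self) -> None:
        (s1, e1), (s2, e2) = self.primer1, self.primer2
        if not (s1 < e1 <= s2 < e2):
            raise ValueError(f"{self.id}: primer footprints must be ordered and disjoint")

    @property
    def reference_length(self) -> int:
        return self.primer2[1] - self.primer1[0]


def predict_amplicons(assay: PCRAssay, sv: SVRecord) -> dict[str, object]:
    """Predicted product size per allele: {"ref": bp, "alt": bp or "no product"}."""
    ref_len = assay.reference_length
    if sv.chrom != assay.chrom:
        warnings.warn(
            f"assay {assay.id}: SV {sv.id} on another chromosome; both alleles reference-length",
            stacklevel=2,
        )
        return {"ref": ref_len, "alt": ref_len}

    s, e = sv.interval()
    (p1s, p1e), (p2s, p2e) = assay.primer1, assay.primer2
    overlaps_primer = (s < p1e and e > p1s) or (s < p2e and e > p2s)
    if sv.svtype == "DEL":
        if overlaps_primer:
            return {"ref": ref_len, "alt": NO_PRODUCT}
        if p1e <= s and e <= p2s:
            return {"ref": ref_len, "alt": ref_len - sv.size}
        if e <= p1s or s >= p2e:
            return {"ref": ref_len, "alt": ref_len}
        # extends beyond the amplicon without touching a footprint is impossible
        return {"ref": ref_len, "alt": NO_PRODUCT}
    # insertion: 1 bp anchor
    if overlaps_primer:
        return {"ref": ref_len, "alt": NO_PRODUCT}
    if p1e <= s < p2s:
        return {"ref": ref_len, "alt": ref_len + sv.size}
    return {"ref": ref_len, "alt": ref_len}


@dataclass
class SegregationTest:
    """1:1 segregation chi-square for one subfamily."""

    count1: int
    count2: int
    chi2: float
    p: float
    stars: str
    subfamily: str = ""


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def segregation_test(count1: int, count2: int, subfamily: str = "") -> SegregationTest:
    """Chi-square goodness of fit against 1:1, one df, no continuity correction."""
    if count1 < 0 or count2 < 0:
        raise ValueError("counts must be non-negative")
    n = count1 + count2
    if n == 0:
        raise ValueError("both counts are zero")
    expected = n / 2.0
    chi2 = (count1 - expected) ** 2 / expected + (count2 - expected) ** 2 / expected
    p = float(stats.chi2.sf(chi2, df=1))
    return SegregationTest(count1, count2, float(chi2), p, _stars(p), subfamily)


@dataclass
class AllelicEffect:
    """Carrier-minus-reference difference in days to flowering, one environment.

    Negative effects mean carriers flower earlier.
    """

    sv: str
    environment: str
    effect: Optional[float]
    t: Optional[float]
    p: Optional[float]
    n_carrier: int
    n_reference: int
    significant: bool
    testable: bool = True


def allelic_effects(
    sv_id: str,
    genotypes: pd.Series,
    phenotypes: pd.DataFrame,
    alpha: float = 0.05,
) -> list[AllelicEffect]:
    """Per-environment allelic effects of one SV with Student's t tests.

    ``genotypes`` maps individual -> 0 (reference) / 1 (carrier);
    ``phenotypes`` is the long table (individual, environment, replicate,
    days).  Within each environment, individuals enter with their entry mean
    over replicates; the effect is mean(carrier) - mean(reference) and the
    p-value a two-sided pooled-variance t test.  An environment with an
    empty genotype class is marked untestable.
    """
    geno = genotypes.dropna()
    effects = []
    for env, sub in phenotypes.groupby("environment", sort=True):
        means = sub.groupby("individual")["days"].mean()
        shared = means.index.intersection(geno.index)
        carrier = means.loc[[i for i in shared if geno[i] == 1]]
        reference = means.loc[[i for i in shared if geno[i] == 0]]
        if carrier.empty or reference.empty:
            effects.append(
                AllelicEffect(sv_id, env, None, None, None, len(carrier), len(reference), False, testable=False)
            )
            continue
        effect = float(carrier.mean() - reference.mean())
        if len(carrier) + len(reference) > 2:
            t, p = stats.ttest_ind(carrier, reference, equal_var=True)
            t, p = float(t), float(p)
            if np.isnan(p):  # zero pooled variance with equal means
                t, p = 0.0, 1.0
        else:
            t, p = None, None
        effects.append(
            AllelicEffect(
                sv_id, env, effect, t, p, len(carrier), len(reference),
                significant=(p is not None and p < alpha),
            )
        )
    return effects


def effects_table(effects: Sequence[AllelicEffect]) -> pd.DataFrame:
    """Per-environment effect table; non-significant effects shown as 'ns'."""
    rows = []
    for e in effects:
        rows.append(
            {
                "sv": e.sv,
                "environment": e.environment,
                "effect_days": np.nan if e.effect is None else round(e.effect, 2),
                "p": np.nan if e.p is None else e.p,
                "display": (
                    "-" if not e.testable else (f"{e.effect:.2f}" if e.significant else "ns")
                ),
                "n_carrier": e.n_carrier,
                "n_reference": e.n_reference,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class NMCCall:
    """Normalized-mean-coverage deletion call for one individual."""

    individual: str
    interval: tuple[str, int, int]
    nmc: float
    call: str  # deletion / reference / ambiguous


def nmc_genotype(
    track: DepthTrack,
    interval: tuple[int, int],
    baseline_intervals: Optional[Sequence[tuple[int, int]]] = None,
    individual: str = "",
    baseline_copies: int = 1,
) -> NMCCall:
    """Call a deletion from the ratio of target to baseline mean depth.

    NMC = mean depth over the target interval / per-copy mean depth over the
    baseline intervals (default baseline: the rest of the track, i.e. the
    flanks).  Boundary values 0.5 and 1.5 are ambiguous.

    ``baseline_copies`` models a genotyping target in which the baseline
    region is present more than once (the modified-reference protocol adds
    the gene body both with and without the deleted sequence, so flanking
    reads split between two copies while the deleted interval is unique).
    The observed baseline mean is divided by ``baseline_copies``; with two
    copies a reference individual scores NMC about 2 and a heterozygote
    about 1, matching the deletion / ambiguous / reference partition used
    for panel screening.
    """
    s, e = interval
    target_mean = track.mean_over(s, e)
    if baseline_intervals is None:
        baseline_intervals = []
        if track.start < s:
            baseline_intervals.append((track.start, s))
        if e < track.end:
            baseline_intervals.append((e, track.end))
    weights, means = [], []
    for bs, be in baseline_intervals:
        bs, be = max(bs, track.start), min(be, track.end)
        if be > bs:
            means.append(track.mean_over(bs, be))
            weights.append(be - bs)
    if not means:
        raise ValueError("uninformative sample: no baseline coverage")
    if baseline_copies < 1:
        raise ValueError("baseline_copies must be a positive integer")
    baseline_mean = float(np.average(means, weights=weights)) / baseline_copies
    if baseline_mean == 0:
        raise ValueError("uninformative sample: zero baseline coverage")
    nmc = target_mean / baseline_mean
    if nmc < NMC_DELETION_BELOW:
        call = "deletion"
    elif nmc > NMC_REFERENCE_ABOVE:
        call = "reference"
    else:
        call = "ambiguous"
    return NMCCall(individual, (track.chrom, s, e), float(nmc), call)


def concordance(
    nmc_calls: Mapping[str, str], pcr_calls: Mapping[str, str]
) -> tuple[pd.DataFrame, float]:
    """Cross-tabulate NMC vs PCR calls and the agreement fraction.

    Rows are NMC classes (deletion/reference/ambiguous), columns PCR classes
    (deletion/reference/heterozygous).  Agreement is computed over shared
    individuals whose NMC call is not ambiguous.
    """
    shared = sorted(set(nmc_calls) & set(pcr_calls))
    if not shared:
        raise ValueError("no shared individuals between call sets")
    table = pd.DataFrame(
        0,
        index=["deletion", "reference", "ambiguous"],
        columns=["deletion", "reference", "heterozygous"],
        dtype=int,
    )
    agree = total = 0
    for ind in shared:
        nmc, pcr = nmc_calls[ind], pcr_calls[ind]
        table.loc[nmc, pcr] += 1
        if nmc != "ambiguous":
            total += 1
            agree += int(nmc == pcr)
    return table, (agree / total if total else np.nan)
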
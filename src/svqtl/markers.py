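"""Marker quality control and SNaP (single nucleotide absence polymorphism) calling.

Array markers whose probe site lies inside a deletion fail systematically in
carrier individuals.  Ordinary QC discards such markers as "too much missing
data"; SNaP calling rescues them by re-reading the failure pattern as a
dominant presence/absence marker, validated by the 1:1 segregation expected
in a DH subfamily.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import CALL_A, CALL_B, CALL_FAILED, CALL_MISSING, GenotypeMatrix


def qc_filter(
    g: GenotypeMatrix,
    max_marker_missing: float = 0.10,
    min_maf: float = 0.05,
    max_individual_missing: float = 0.10,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Exclude high-missingness individuals/markers and low-MAF markers.

    Missingness counts both missing and failed calls.  Individuals are
    filtered before marker statistics are computed; the passes are iterated
    to a fixed point so the operation is idempotent.  Returns the filtered
    matrix and an exclusion report (kind, id, reason, value).

    Raises ``ValueError`` if no markers survive.
    """
    if g.n_markers == 0 or g.n_individuals == 0:
        raise ValueError("genotype matrix is empty")
    report_rows = []
    current = g
    while True:
        ind_miss = current.individual_missingness()
        drop_ind = ind_miss[ind_miss > max_individual_missing]
        if not drop_ind.empty:
            for ind, v in drop_ind.items():
                report_rows.append({"kind": "individual", "id": ind, "reason": "missingness", "value": v})
            keep = ~current.individual_ids.isin(drop_ind.index)
            if not keep.any():
                raise ValueError("no individuals survive QC")
            current = current.select_individuals(np.asarray(keep))
            continue

        miss = current.marker_missingness()
        maf = current.maf()
        drop_miss = miss > max_marker_missing
        drop_maf = ~drop_miss & (maf.fillna(0.0) < min_maf)
        if drop_miss.any() or drop_maf.any():
            for mid in miss.index[drop_miss]:
                report_rows.append({"kind": "marker", "id": mid, "reason": "missingness", "value": miss[mid]})
            for mid in maf.index[drop_maf]:
                report_rows.append({"kind": "marker", "id": mid, "reason": "maf", "value": maf[mid]})
            keep = ~(drop_miss | drop_maf).to_numpy()
            if not keep.any():
                raise ValueError("no markers survive QC")
            current = current.select_markers(keep)
            continue
        break

    report = pd.DataFrame(report_rows, columns=["kind", "id", "reason", "value"])
    return current, report


@dataclass
class SNaPMarker:
    """A presence/absence marker derived from systematic array-call failure."""

    marker: str
    counts: Mapping[str, tuple[int, int]]  # subfamily -> (presence, absence)
    pvalues: Mapping[str, float]  # polymorphic subfamilies only
    accepted: bool


def _one_to_one_chi2(a: int, b: int) -> tuple[float, float]:
    """1-df goodness-of-fit chi-square against 1:1, no continuity correction."""
    n = a + b
    chi2 = (a - b) ** 2 / n
    return chi2, float(stats.chi2.sf(chi2, df=1))


def call_snap(
    g: GenotypeMatrix,
    min_fail_rate: float = 0.10,
    alpha: float = 0.05,
    mode: str = "all",
) -> tuple[list[SNaPMarker], GenotypeMatrix]:
    """Call SNaP markers from failure patterns and recode them as dominant calls.

    A marker is a candidate when its failed-call fraction is at least
    ``min_fail_rate`` (i.e. it failed ordinary QC for systematic failures).
    Within each subfamily where both presence (called) and absence (failed)
    occur, the counts are tested against 1:1.  A candidate is accepted when
    at least one subfamily is polymorphic and — under ``mode="all"`` — every
    polymorphic subfamily fits 1:1 at level ``alpha`` (``mode="any"``
    requires only one fitting subfamily).  Candidates monomorphic in all
    subfamilies are dropped silently.

    Accepted markers are recoded presence=A / absence=B (missing preserved)
    with marker ids suffixed ``_SNaP``; individual count and subfamily
    labels are unchanged.
    """
    if mode not in ("all", "any"):
        raise ValueError("mode must be 'all' or 'any'")
    if "subfamily" not in g.individuals.columns:
        raise ValueError("individuals need subfamily labels")
    subfam = g.subfamilies.to_numpy()
    families = list(dict.fromkeys(subfam))
    fail_rate = g.marker_fail_rate()

    snaps: list[SNaPMarker] = []
    accepted_rows = []
    for mi, marker in enumerate(g.marker_ids):
        if fail_rate.iloc[mi] < min_fail_rate:
            continue
        row = g.calls[mi]
        counts, pvalues = {}, {}
        for fam in families:
            cells = row[subfam == fam]
            presence = int((cells >= 0).sum())
            absence = int((cells == CALL_FAILED).sum())
            counts[fam] = (presence, absence)
            if presence > 0 and absence > 0:
                _, p = _one_to_one_chi2(presence, absence)
                pvalues[fam] = p
        if not pvalues:
            continue  # monomorphic in every subfamily: nothing to map
        fits = [p >= alpha for p in pvalues.values()]
        accepted = all(fits) if mode == "all" else any(fits)
        snaps.append(SNaPMarker(marker, counts, pvalues, accepted))
        if accepted:
            accepted_rows.append(mi)

    recoded_calls = np.full((len(accepted_rows), g.n_individuals), CALL_MISSING, dtype=np.int8)
    for out_i, mi in enumerate(accepted_rows):
        row = g.calls[mi]
        recoded_calls[out_i, row >= 0] = CALL_A
        recoded_calls[out_i, row == CALL_FAILED] = CALL_B
    markers = g.markers.iloc[accepted_rows].copy()
    markers.index = [f"{m}_SNaP" for m in markers.index]
    recoded = GenotypeMatrix(recoded_calls, markers, g.individuals.copy())
    return snaps, recoded


def snap_report(snaps: list[SNaPMarker]) -> pd.DataFrame:
    """Long-format SNaP table (marker, subfamily, presence, absence, p, accepted)."""
    rows = []
    for s in snaps:
        for fam, (presence, absence) in s.counts.items():
            rows.append(
                {
                    "marker": s.marker,
                    "subfamily": fam,
                    "presence": presence,
                    "absence": absence,
                    "p": s.pvalues.get(fam, np.nan),
                    "accepted": s.accepted,
                }
            )
    return pd.DataFrame(rows, columns=["marker", "subfamily", "presence", "absence", "p", "accepted"])
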
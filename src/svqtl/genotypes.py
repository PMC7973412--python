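"""Core containers: coded genotype matrices and genetic maps.

A :class:`GenotypeMatrix` holds array-style allele calls for fully homozygous
(doubled-haploid or inbred) individuals.  Each cell is one of four states:

* ``CALL_A`` / ``CALL_B`` — the two alleles of a biallelic marker,
* ``CALL_MISSING`` — randomly missing data,
* ``CALL_FAILED`` — a systematically failed assay call.

Failed calls are kept distinct from missing data because presence/absence
(SNaP) marker calling interprets systematic call failure as a deleted probe
site, while quality control treats both as missingness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CALL_A = 0
CALL_B = 1
CALL_MISSING = -1
CALL_FAILED = -2

CALL_LABELS = {CALL_A: "A", CALL_B: "B", CALL_MISSING: "NA", CALL_FAILED: "FAIL"}
LABEL_CALLS = {v: k for k, v in CALL_LABELS.items()}


@dataclass
class GenotypeMatrix:
    """Markers x individuals coded allele calls.

    Parameters
    ----------
    calls
        ``(n_markers, n_individuals)`` integer array with values in
        ``{CALL_A, CALL_B, CALL_MISSING, CALL_FAILED}``.
    markers
        Frame indexed by unique marker id with columns ``chrom``, ``bp``
        (1-based physical position) and optionally ``cm``.
    individuals
        Frame indexed by unique individual id with a ``subfamily`` column.
    """

    calls: np.ndarray
    markers: pd.DataFrame
    individuals: pd.DataFrame

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D markers x individuals array")
        if self.calls.shape != (len(self.markers), len(self.individuals)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.markers)} markers x {len(self.individuals)} individuals"
            )
        if not self.markers.index.is_unique:
            raise ValueError("marker identifiers must be unique")
        if not self.individuals.index.is_unique:
            raise ValueError("individual identifiers must be unique")
        valid = np.isin(self.calls, (CALL_A, CALL_B, CALL_MISSING, CALL_FAILED))
        if not valid.all():
            bad = np.unique(self.calls[~valid])
            raise ValueError(f"invalid call codes: {bad.tolist()}")

    # -- basic introspection -------------------------------------------------

    @property
    def n_markers(self) -> int:
        return self.calls.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[1]

    @property
    def marker_ids(self) -> pd.Index:
        return self.markers.index

    @property
    def individual_ids(self) -> pd.Index:
        return self.individuals.index

    @property
    def subfamilies(self) -> pd.Series:
        return self.individuals["subfamily"]

    def called_mask(self) -> np.ndarray:
        """Boolean mask of cells carrying an actual allele call."""
        return self.calls >= 0

    # -- summary statistics --------------------------------------------------

    def marker_missingness(self) -> pd.Series:
        """Per-marker fraction of cells that are missing or failed."""
        frac = (~self.called_mask()).mean(axis=1)
        return pd.Series(frac, index=self.marker_ids, name="missingness")

    def marker_fail_rate(self) -> pd.Series:
        """Per-marker fraction of systematically failed calls only."""
        frac = (self.calls == CALL_FAILED).mean(axis=1)
        return pd.Series(frac, index=self.marker_ids, name="fail_rate")

    def individual_missingness(self) -> pd.Series:
        frac = (~self.called_mask()).mean(axis=0)
        return pd.Series(frac, index=self.individual_ids, name="missingness")

    def maf(self) -> pd.Series:
        """Minor allele frequency among called cells (NaN if nothing called)."""
        called = self.called_mask()
        n_called = called.sum(axis=1)
        n_b = ((self.calls == CALL_B) & called).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            f_b = np.where(n_called > 0, n_b / np.maximum(n_called, 1), np.nan)
        maf = np.minimum(f_b, 1.0 - f_b)
        return pd.Series(maf, index=self.marker_ids, name="maf")

    # -- subsetting ----------------------------------------------------------

    def select_markers(self, which) -> "GenotypeMatrix":
        """Subset by marker ids or a boolean mask (order preserved)."""
        idx = self._resolve(which, self.marker_ids)
        return GenotypeMatrix(
            self.calls[idx, :].copy(), self.markers.iloc[idx].copy(), self.individuals.copy()
        )

    def select_individuals(self, which) -> "GenotypeMatrix":
        idx = self._resolve(which, self.individual_ids)
        return GenotypeMatrix(
            self.calls[:, idx].copy(), self.markers.copy(), self.individuals.iloc[idx].copy()
        )

    @staticmethod
    def _resolve(which, index: pd.Index) -> np.ndarray:
        which = np.asarray(which)
        if which.dtype == bool:
            if which.shape != (len(index),):
                raise ValueError("boolean mask length mismatch")
            return np.flatnonzero(which)
        pos = index.get_indexer(which)
        if (pos < 0).any():
            missing = which[pos < 0]
            raise KeyError(f"unknown identifiers: {list(missing)[:5]}")
        return pos

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.calls.copy(), self.markers.copy(), self.individuals.copy())

    def to_frame(self) -> pd.DataFrame:
        """Human-readable frame of call labels (markers x individuals)."""
        labels = np.vectorize(CALL_LABELS.get)(self.calls)
        return pd.DataFrame(labels, index=self.marker_ids, columns=self.individual_ids)


@dataclass
class GeneticMap:
    """Ordered marker map with physical (bp) and genetic (cM) coordinates.

    ``table`` is indexed by marker id with columns ``chrom``, ``bp`` and
    ``cm``.  Within each chromosome bp must be strictly increasing and cM
    non-decreasing.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"chrom", "bp", "cm"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"map table needs columns {sorted(required)}")
        if not self.table.index.is_unique:
            raise ValueError("marker identifiers must be unique")
        for chrom, sub in self.table.groupby("chrom", sort=False):
            bp = sub["bp"].to_numpy()
            cm = sub["cm"].to_numpy()
            if not (np.diff(bp) > 0).all():
                raise ValueError(f"bp positions not strictly increasing on {chrom}")
            if not (np.diff(cm) >= 0).all():
                raise ValueError(f"cM positions not monotone on {chrom}")

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.table["chrom"]))

    def markers_on(self, chrom: str) -> pd.DataFrame:
        return self.table[self.table["chrom"] == chrom]

    def length_cm(self, chrom: str) -> float:
        return float(self.markers_on(chrom)["cm"].max())

    def extent_bp(self, chrom: str) -> tuple[int, int]:
        sub = self.markers_on(chrom)
        return int(sub["bp"].min()), int(sub["bp"].max())

    def interpolate_cm(self, chrom: str, bp) -> np.ndarray:
        """Genetic position of arbitrary physical coordinates on ``chrom``."""
        sub = self.markers_on(chrom)
        if sub.empty:
            raise KeyError(f"chromosome {chrom!r} not on the map")
        return np.interp(np.asarray(bp, dtype=float), sub["bp"], sub["cm"])

    @classmethod
    def dense(
        cls,
        chrom_sizes_bp: Mapping[str, int],
        spacing_bp: int = 50_000,
        cm_per_mb: float = 2.0,
        start_bp: int = 1,
    ) -> "GeneticMap":
        """Evenly spaced markers with a linear bp->cM relation per chromosome."""
        rows = []
        for chrom, size in chrom_sizes_bp.items():
            positions = np.arange(start_bp, int(size) + 1, int(spacing_bp))
            for i, bp in enumerate(positions):
                rows.append(
                    {
                        "marker": f"{chrom}_m{i + 1:04d}",
                        "chrom": chrom,
                        "bp": int(bp),
                        "cm": (bp - start_bp) / 1e6 * cm_per_mb,
                    }
                )
        table = pd.DataFrame(rows).set_index("marker")
        return cls(table)
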
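"""Transcription-factor binding-site scanning with JASPAR position matrices.

Position frequency matrices (PFMs) are parsed from JASPAR-format text
(via Bio.motifs) and converted to log-odds score matrices with a
background-distributed pseudocount (JASPAR convention, total 0.8 by
default).  Both strands of a query sequence are scanned; hits are reported
with the relative score (score - min) / (max - min), which is 1 exactly for
the consensus sequence.  Windows containing N are skipped.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT_ORDER = [3, 2, 1, 0]  # A<->T, C<->G

DEFAULT_PSEUDOCOUNT = 0.8
DEFAULT_BACKGROUND = (0.25, 0.25, 0.25, 0.25)


@dataclass
class PFM:
    """A position frequency matrix and its derived log-odds scorer."""

    name: str
    counts: np.ndarray  # (4, L), rows A, C, G, T
    background: tuple[float, float, float, float] = DEFAULT_BACKGROUND
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4 or self.counts.shape[1] < 1:
            raise ValueError(f"{self.name}: counts must be a 4 x L matrix with L >= 1")
        if (self.counts < 0).any():
            raise ValueError(f"{self.name}: counts must be non-negative")
        if (self.counts.sum(axis=0) <= 0).any():
            raise ValueError(f"{self.name}: every column needs a positive total")
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0) or (bg <= 0).any():
            raise ValueError("background must be four positive frequencies summing to 1")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @cached_property
    def log_odds(self) -> np.ndarray:
        """log2( p(base|position) / background ), pseudocount spread by background."""
        bg = np.asarray(self.background)[:, None]
        adjusted = self.counts + self.pseudocount * bg
        probs = adjusted / adjusted.sum(axis=0, keepdims=True)
        return np.log2(probs / bg)

    @cached_property
    def score_range(self) -> tuple[float, float]:
        lo = self.log_odds
        return float(lo.min(axis=0).sum()), float(lo.max(axis=0).sum())

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.counts.argmax(axis=0))

    def relative(self, score: float) -> float:
        smin, smax = self.score_range
        return (score - smin) / (smax - smin)


def _validate_jaspar_rows(text: str) -> None:
    """Check matrix rows for equal length and non-negative numbers.

    Delegating semantics to Bio.motifs; this pre-pass reports the offending
    line number for malformed input.
    """
    lengths: dict[str, int] = {}  # per record
    record = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith(">"):
            record += 1
            lengths.pop("n", None)
            continue
        inner = stripped
        if "[" in inner:
            inner = inner.split("[", 1)[1].rsplit("]", 1)[0]
            inner_fields = inner.split()
        else:
            inner_fields = inner.split()
            if inner_fields and inner_fields[0].upper() in ("A", "C", "G", "T"):
                inner_fields = inner_fields[1:]
        try:
            values = [float(v) for v in inner_fields]
        except ValueError as exc:
            raise ValueError(f"line {lineno}: non-numeric matrix entry") from exc
        if any(v < 0 for v in values):
            raise ValueError(f"line {lineno}: negative count")
        n = lengths.setdefault("n", len(values))
        if len(values) != n:
            raise ValueError(f"line {lineno}: row length {len(values)} != {n}")


def load_pfms(
    source: Union[str, io.TextIOBase],
    background: tuple[float, float, float, float] = DEFAULT_BACKGROUND,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> list[PFM]:
    """Parse all matrices from JASPAR-format text, a path, or a handle."""
    if isinstance(source, str):
        if "\n" not in source and not source.lstrip().startswith(">"):
            with open(source) as fh:
                text = fh.read()
        else:
            text = source
    else:
        text = source.read()
    _validate_jaspar_rows(text)
    parsed = bio_motifs.parse(io.StringIO(text), "jaspar")
    pfms = []
    for m in parsed:
        counts = np.array([list(m.counts[b]) for b in BASES], dtype=float)
        name = m.name or m.matrix_id or "motif"
        pfms.append(PFM(name=name, counts=counts, background=background, pseudocount=pseudocount))
    return pfms


def load_pfm(source, **kwargs) -> PFM:
    """Parse exactly one JASPAR matrix."""
    pfms = load_pfms(source, **kwargs)
    if len(pfms) != 1:
        raise ValueError(f"expected one matrix, found {len(pfms)}")
    return pfms[0]


def write_pfm(pfm: PFM) -> str:
    """Serialize a PFM back to JASPAR text (round-trips counts exactly)."""
    lines = [f">{pfm.name}"]
    for i, base in enumerate(BASES):
        values = " ".join(f"{v:.0f}" if v == int(v) else f"{v}" for v in pfm.counts[i])
        lines.append(f"{base} [ {values} ]")
    return "\n".join(lines) + "\n"


def make_pfm_from_consensus(name: str, consensus: str, weight: float = 20.0, off: float = 1.0) -> PFM:
    """Synthetic PFM concentrated on a consensus sequence (for demos/tests)."""
    consensus = consensus.upper()
    counts = np.full((4, len(consensus)), off)
    for j, base in enumerate(consensus):
        counts[_BASE_INDEX[base], j] = weight
    return PFM(name=name, counts=counts)


@dataclass
class MotifHit:
    """One motif match on the query sequence (position 0-based, window start)."""

    motif: str
    position: int
    strand: str
    score: float
    rel_score: float


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    codes = np.full(arr.shape, -1, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        codes[arr == ord(base)] = idx
    unknown = (codes == -1) & (arr != ord("N"))
    if unknown.any():
        bad = chr(arr[unknown][0])
        raise ValueError(f"sequence contains invalid character {bad!r}")
    return codes


def scan(seq: str, pfm: PFM, min_rel_score: float = 0.8) -> list[MotifHit]:
    """Scan both strands for windows with relative score >= threshold.

    Returns hits sorted by position (then strand).  Positions always refer
    to the forward strand of the query; a minus-strand hit at position i
    means the reverse complement of ``seq[i:i+L]`` matches the motif.
    """
    codes = _encode(seq)
    L = pfm.length
    n = len(codes) - L + 1
    if n <= 0:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    valid = (windows >= 0).all(axis=1)

    lo = pfm.log_odds
    rc_lo = lo[_COMPLEMENT_ORDER, :][:, ::-1]
    safe = np.where(windows >= 0, windows, 0)
    cols = np.arange(L)
    plus = lo[safe, cols].sum(axis=1)
    minus = rc_lo[safe, cols].sum(axis=1)

    hits = []
    smin, smax = pfm.score_range
    span = smax - smin
    for strand, scores in (("+", plus), ("-", minus)):
        rel = (scores - smin) / span
        for pos in np.flatnonzero(valid & (rel >= min_rel_score)):
            hits.append(MotifHit(pfm.name, int(pos), strand, float(scores[pos]), float(rel[pos])))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def hits_table(hits: Sequence[MotifHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "motif": h.motif,
                "position": h.position,
                "strand": h.strand,
                "score": h.score,
                "rel_score": h.rel_score,
            }
            for h in hits
        ],
        columns=["motif", "position", "strand", "score", "rel_score"],
    )
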
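"""Genomic interval and signal-track I/O, and promoter classification.

Active promoters are taken to be DNase hypersensitive sites (DHSs).  Each DHS
peak is reduced to a single representative coordinate (the peak midpoint) and
assigned one of three firing states by overlap with a ChromHMM-style
segmentation: state 1 marks active genic promoters, states 4 and 5 mark
active non-genic promoters (enhancers and other non-genic RNAs), and DHSs
overlapping none of these states form the *other* class.

Coordinates are 0-based half-open (BED convention) throughout; strand is
ignored everywhere, as the underlying model is strandless.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "PromoterState",
    "GenomicInterval",
    "Promoter",
    "SignalTrack",
    "BedParseError",
    "read_bed",
    "write_bed",
    "read_signal",
    "write_signal",
    "classify_promoters",
    "hmm_state_number",
    "write_promoters",
    "read_promoters",
]

#: ChromHMM state marking active genic promoters.
GENIC_STATES = frozenset({1})
#: ChromHMM states marking active non-genic promoters (enhancers, eRNAs).
NON_GENIC_STATES = frozenset({4, 5})

DEFAULT_BIN_SIZE = 3000

_HEADER_PREFIXES = ("track", "browser", "#")


class PromoterState(enum.Enum):
    """Firing class of an active promoter."""

    GENIC = "GENIC"
    NON_GENIC = "NON_GENIC"
    OTHER = "OTHER"


class BedParseError(ValueError):
    """Raised for malformed BED/bedGraph lines; message names the line number."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) with an optional label."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must be > start ({self.start})")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Promoter:
    """An active promoter: one representative bp coordinate plus firing state."""

    chrom: str
    pos: int
    state: PromoterState
    id: str

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"pos must be >= 0, got {self.pos}")
        if not isinstance(self.state, PromoterState):
            raise TypeError(f"state must be a PromoterState, got {self.state!r}")


@dataclass
class SignalTrack:
    """A fixed-bin-width, single-chromosome signal profile.

    Bin ``k`` covers ``[k*bin_size, (k+1)*bin_size)``.  Values are
    non-negative; this is a coarse-grained stand-in for a nascent-transcription
    profile such as GRO-seq binned at 3 kbp.
    """

    chrom: str
    bin_size: int = DEFAULT_BIN_SIZE
    values: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be > 0")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be 1-D")
        if np.any(self.values < 0):
            raise ValueError("signal values must be >= 0")

    @property
    def n_bins(self) -> int:
        return int(self.values.size)

    @property
    def extent(self) -> int:
        """Last covered coordinate (bp)."""
        return self.n_bins * self.bin_size

    def bin_index(self, pos: int) -> int:
        if pos < 0 or pos >= self.extent:
            raise IndexError(
                f"position {pos} outside track extent [0, {self.extent}) on {self.chrom}"
            )
        return pos // self.bin_size

    def value_at(self, pos: int) -> float:
        return float(self.values[self.bin_index(pos)])


# ---------------------------------------------------------------------------
# BED / bedGraph I/O
# ---------------------------------------------------------------------------

def _data_lines(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(_HEADER_PREFIXES):
                continue
            yield lineno, line.split()


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a whitespace-delimited BED3+ file into intervals (file order).

    Track/browser/comment header lines are skipped.  Column 4, when present,
    is stored as the interval label (peak id or HMM state name).
    """
    intervals: list[GenomicInterval] = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise BedParseError(f"{path}, line {lineno}: expected >= 3 columns")
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise BedParseError(
                f"{path}, line {lineno}: non-integer coordinates {fields[1]!r}, {fields[2]!r}"
            ) from exc
        label = fields[3] if len(fields) > 3 else ""
        try:
            intervals.append(GenomicInterval(fields[0], start, end, label))
        except ValueError as exc:
            raise BedParseError(f"{path}, line {lineno}: {exc}") from exc
    return intervals


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.label:
                cols.append(iv.label)
            fh.write("\t".join(cols) + "\n")


def read_signal(
    path: str | Path,
    bin_size: int = DEFAULT_BIN_SIZE,
    chrom: str | None = None,
) -> SignalTrack:
    """Read a 4-column bedGraph and sum it into fixed-width bins.

    Records partially overlapping a bin contribute in proportion to the
    overlapped length, so total signal mass is conserved.  The file must
    describe a single chromosome unless ``chrom`` selects one.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    records: list[tuple[int, int, float]] = []
    seen_chrom: str | None = None
    for lineno, fields in _data_lines(path):
        if len(fields) < 4:
            raise BedParseError(f"{path}, line {lineno}: expected 4 bedGraph columns")
        c = fields[0]
        if chrom is not None and c != chrom:
            continue
        if seen_chrom is None:
            seen_chrom = c
        elif c != seen_chrom:
            raise BedParseError(
                f"{path}, line {lineno}: multiple chromosomes ({seen_chrom}, {c}); "
                "pass chrom= to select one"
            )
        try:
            start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
        except ValueError as exc:
            raise BedParseError(f"{path}, line {lineno}: malformed record") from exc
        if end <= start:
            raise BedParseError(f"{path}, line {lineno}: end <= start")
        if value < 0:
            raise BedParseError(f"{path}, line {lineno}: negative signal value {value}")
        records.append((start, end, value))
    if seen_chrom is None:
        return SignalTrack(chrom=chrom or "", bin_size=bin_size, values=np.zeros(0))

    max_end = max(end for _, end, _ in records)
    n_bins = math.ceil(max_end / bin_size)
    values = np.zeros(n_bins)
    for start, end, value in records:
        density = value / (end - start)  # signal per bp, prorated
        b0, b1 = start // bin_size, (end - 1) // bin_size
        for b in range(b0, b1 + 1):
            lo = max(start, b * bin_size)
            hi = min(end, (b + 1) * bin_size)
            values[b] += density * (hi - lo)
    return SignalTrack(chrom=seen_chrom, bin_size=bin_size, values=values)


def write_signal(track: SignalTrack, path: str | Path) -> None:
    """Write one bedGraph record per non-zero bin."""
    with open(path, "w") as fh:
        for k, v in enumerate(track.values):
            if v != 0:
                fh.write(
                    f"{track.chrom}\t{k * track.bin_size}\t{(k + 1) * track.bin_size}\t{v:.10g}\n"
                )


# ---------------------------------------------------------------------------
# Promoter classification
# ---------------------------------------------------------------------------

def hmm_state_number(label: str) -> int | None:
    """Parse the leading integer of an HMM state label ('1_Active_Promoter' -> 1)."""
    digits = ""
    for ch in label:
        if ch.isdigit():
            digits += ch
        else:
            break
    return int(digits) if digits else None


def classify_promoters(
    dhs: Sequence[GenomicInterval],
    hmm: Sequence[GenomicInterval],
) -> list[Promoter]:
    """Assign a firing state to every DHS peak by overlap with HMM segments.

    A peak overlapping (>= 1 bp) a state-1 segment is GENIC; otherwise a peak
    overlapping a state-4 or state-5 segment is NON_GENIC; all remaining peaks
    are OTHER.  The representative coordinate is the peak midpoint.  Peaks
    whose midpoints coincide are merged (keeping the highest-precedence
    state), since downstream distances diverge at l=0.

    Returns one promoter per surviving peak, sorted by (chrom, pos).
    """
    if not dhs:
        return []
    dhs_chroms = {iv.chrom for iv in dhs}
    hmm_chroms = {iv.chrom for iv in hmm}
    if hmm and dhs_chroms.isdisjoint(hmm_chroms):
        raise ValueError(
            f"DHS chromosomes {sorted(dhs_chroms)} and HMM chromosomes "
            f"{sorted(hmm_chroms)} are disjoint; no classification possible"
        )

    trees: dict[str, IntervalTree] = {}
    for seg in hmm:
        state = hmm_state_number(seg.label)
        if state is None:
            raise ValueError(f"HMM segment label {seg.label!r} has no leading state number")
        trees.setdefault(seg.chrom, IntervalTree()).addi(seg.start, seg.end, state)

    precedence = {PromoterState.GENIC: 0, PromoterState.NON_GENIC: 1, PromoterState.OTHER: 2}
    best: dict[tuple[str, int], tuple[PromoterState, str]] = {}
    for i, peak in enumerate(dhs):
        states = {
            hit.data for hit in trees.get(peak.chrom, IntervalTree()).overlap(peak.start, peak.end)
        }
        if states & GENIC_STATES:
            state = PromoterState.GENIC
        elif states & NON_GENIC_STATES:
            state = PromoterState.NON_GENIC
        else:
            state = PromoterState.OTHER
        key = (peak.chrom, peak.midpoint)
        pid = peak.label or f"{peak.chrom}:{peak.midpoint}"
        if key not in best or precedence[state] < precedence[best[key][0]]:
            best[key] = (state, pid)
    return [
        Promoter(chrom=c, pos=p, state=s, id=pid)
        for (c, p), (s, pid) in sorted(best.items())
    ]


# ---------------------------------------------------------------------------
# Promoter table I/O (TSV)
# ---------------------------------------------------------------------------

def write_promoters(promoters: Sequence[Promoter], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "chrom": [p.chrom for p in promoters],
            "pos": [p.pos for p in promoters],
            "state": [p.state.value for p in promoters],
            "id": [p.id for p in promoters],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_promoters(path: str | Path) -> list[Promoter]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "id": str})
    return [
        Promoter(chrom=r.chrom, pos=int(r.pos), state=PromoterState(r.state), id=str(r.id))
        for r in df.itertuples()
    ]
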
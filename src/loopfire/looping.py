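"""The looping formula: relative promoter firing probability from genomic distance.

The firing probability of promoter *i* is dominated by two configurations:
direct binding of *i* to a transcription factory, and tethering of *i* near a
factory through a loop to its nearest appropriate promoter.  Summing the two
Boltzmann weights under fractal-globule looping statistics (contact
probability ~ a/l) gives the relative firing probability

    ptrans(i) ~ b * (1 + c / l(i)),

where ``l(i)`` is the genomic distance in bp to the nearest appropriate
promoter, and ``b`` and ``c`` are positive constants absorbing TF:pol
concentration, promoter affinity, and looping statistics.  Only ratios and
rank orders of ptrans are meaningful; the partition function is never
computed.

Two variants are implemented:

* **1-state** — all active promoters are equivalent: ``b`` is common (and so
  irrelevant for ranking) and ``l`` is the distance to the nearest active
  promoter of any class.
* **3-state** — promoters carry class weights ``b_g >= b_ng >= b_o`` (genic,
  non-genic, other) estimated from nascent-transcription signal, and the loop
  always goes to the nearest *genic* promoter; with no other genic promoter
  on the chromosome the loop term is dropped.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .tracks import Promoter, PromoterState, SignalTrack

__all__ = [
    "Mode",
    "LoopingParams",
    "BoltzmannParams",
    "FiringPrediction",
    "nearest_active_distance",
    "nearest_genic_distance",
    "ptrans_formula",
    "loop_weight_ratio",
    "boltzmann_weights",
    "boltzmann_ptrans",
    "predict",
    "estimate_state_weights",
    "write_predictions",
    "read_predictions",
]

#: Default looping constant: the mean loop contour length measured in HeLa, bp.
DEFAULT_C = 86_000.0
#: Default state weights, the ratios of mean GRO-seq signal per promoter class
#: on human chromosome 14 (HUVEC), normalised to the *other* class.
DEFAULT_B_G, DEFAULT_B_NG, DEFAULT_B_O = 13.1, 3.3, 1.0


class Mode(enum.Enum):
    ONE_STATE = "one_state"
    THREE_STATE = "three_state"


@dataclass(frozen=True)
class LoopingParams:
    """Parameters of the looping formula.

    c : looping constant in bp (loop term weight c/l).
    b_g, b_ng, b_o : dimensionless class weights (3-state mode only).
    mode : ONE_STATE or THREE_STATE.
    """

    c: float = DEFAULT_C
    b_g: float = DEFAULT_B_G
    b_ng: float = DEFAULT_B_NG
    b_o: float = DEFAULT_B_O
    mode: Mode = Mode.THREE_STATE

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("c must be > 0")
        for name in ("b_g", "b_ng", "b_o"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def b_for(self, state: PromoterState) -> float:
        if self.mode is Mode.ONE_STATE:
            return 1.0
        return {
            PromoterState.GENIC: self.b_g,
            PromoterState.NON_GENIC: self.b_ng,
            PromoterState.OTHER: self.b_o,
        }[state]


@dataclass(frozen=True)
class BoltzmannParams:
    """Microscopic parameters of the two-diagram Boltzmann derivation.

    beta_eps : TF:pol–promoter affinity βϵ (kBT units, dimensionless).
    n : TF:pol copy number.
    a : fractal-globule looping prefactor (bp); contact probability p(l)=a/l.
    Z : partition-function normaliser (arbitrary positive scale).
    """

    beta_eps: float
    n: float = 1.0
    a: float = 1.0
    Z: float = 1.0

    def __post_init__(self) -> None:
        if self.n <= 0 or self.a <= 0 or self.Z <= 0:
            raise ValueError("n, a and Z must all be > 0")

    @property
    def equivalent_b(self) -> float:
        """b of the reduced formula: n·e^{βϵ}/Z."""
        return self.n * math.exp(self.beta_eps) / self.Z

    @property
    def equivalent_c(self) -> float:
        """c of the reduced formula: (e^{βϵ}−1)·a, in bp."""
        return (math.exp(self.beta_eps) - 1.0) * self.a


@dataclass(frozen=True)
class FiringPrediction:
    promoter_id: str
    chrom: str
    pos: int
    state: PromoterState
    l_used: float | None  # bp; None when no tethering promoter exists
    ptrans: float
    rank: float  # 1 = highest ptrans; ties averaged


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def _check_sorted_same_chrom(promoters: Sequence[Promoter]) -> None:
    chroms = {p.chrom for p in promoters}
    if len(chroms) > 1:
        raise ValueError(f"promoters span multiple chromosomes: {sorted(chroms)}")
    positions = [p.pos for p in promoters]
    if positions != sorted(positions):
        raise ValueError("promoters must be sorted by position")


def nearest_active_distance(promoters: Sequence[Promoter], i: int) -> float | None:
    """Distance in bp from promoter ``i`` to the nearest other promoter.

    Any state is eligible as a neighbour (1-state rule).  Returns None when
    ``i`` is the only promoter on the chromosome.
    """
    _check_sorted_same_chrom(promoters)
    n = len(promoters)
    if n < 2:
        return None
    pos = promoters[i].pos
    cands = []
    if i > 0:
        cands.append(pos - promoters[i - 1].pos)
    if i < n - 1:
        cands.append(promoters[i + 1].pos - pos)
    return float(min(cands))


def nearest_genic_distance(promoters: Sequence[Promoter], i: int) -> float | None:
    """Distance in bp from promoter ``i`` to the nearest genic promoter != i.

    Returns None (ABSENT) when no other genic promoter exists on the
    chromosome — the loop diagram is then dropped upstream.
    """
    _check_sorted_same_chrom(promoters)
    pos = promoters[i].pos
    dists = [
        abs(p.pos - pos)
        for j, p in enumerate(promoters)
        if j != i and p.state is PromoterState.GENIC
    ]
    return float(min(dists)) if dists else None


# ---------------------------------------------------------------------------
# The formula and its Boltzmann oracle
# ---------------------------------------------------------------------------

def ptrans_formula(l: float | None, b: float = 1.0, c: float = DEFAULT_C) -> float:
    """Relative firing probability b·(1 + c/l); b alone when l is absent."""
    if b <= 0 or c <= 0:
        raise ValueError("b and c must be > 0")
    if l is None:
        return b
    if l == 0:
        raise ValueError("l = 0: coincident promoters must be merged upstream")
    if l < 0:
        raise ValueError("l must be > 0")
    return b * (1.0 + c / l)


def loop_weight_ratio(l: float, c: float = DEFAULT_C) -> float:
    """Weight of the looped diagram relative to the unlooped one: c/l."""
    if l <= 0 or c <= 0:
        raise ValueError("l and c must be > 0")
    return c / l


def boltzmann_weights(params: BoltzmannParams, l: float) -> tuple[float, float]:
    """(unlooped, looped) Boltzmann weights for the two diagrams.

    Unlooped: n·e^{βϵ}·(1 − p(l)); looped: n·e^{2βϵ}·p(l), with p(l) = a/l the
    fractal-globule contact probability.
    """
    if l <= 0:
        raise ValueError("l must be > 0")
    p_loop = params.a / l
    if p_loop >= 1.0:
        raise ValueError(
            f"looping probability a/l = {p_loop:.3g} >= 1; prefactor a invalid at l={l}"
        )
    w = params.n * math.exp(params.beta_eps)
    return w * (1.0 - p_loop), w * math.exp(params.beta_eps) * p_loop


def boltzmann_ptrans(params: BoltzmannParams, l: float) -> float:
    """Firing probability from the two-diagram weight sum, normalised by Z.

    Equals ``ptrans_formula(l, b, c)`` exactly under b = n·e^{βϵ}/Z and
    c = (e^{βϵ}−1)·a.
    """
    unlooped, looped = boltzmann_weights(params, l)
    return (unlooped + looped) / params.Z


# ---------------------------------------------------------------------------
# Genome-scale prediction
# ---------------------------------------------------------------------------

def _predict_one_chrom(
    promoters: Sequence[Promoter], params: LoopingParams
) -> list[tuple[Promoter, float | None, float]]:
    out = []
    for i, p in enumerate(promoters):
        if params.mode is Mode.ONE_STATE:
            l = nearest_active_distance(promoters, i)
        else:
            l = nearest_genic_distance(promoters, i)
        out.append((p, l, ptrans_formula(l, params.b_for(p.state), params.c)))
    return out


def predict(
    promoters: Sequence[Promoter], params: LoopingParams | None = None
) -> list[FiringPrediction]:
    """Apply the looping formula to classified promoters and rank them.

    Distances are computed per chromosome (the model has no trans contacts);
    ranks are tie-averaged over the whole input, rank 1 = highest ptrans.
    Input must be sorted by (chrom, pos).
    """
    if not promoters:
        raise ValueError("no promoters to predict")
    params = params or LoopingParams()

    rows: list[tuple[Promoter, float | None, float]] = []
    by_chrom: dict[str, list[Promoter]] = {}
    for p in promoters:
        by_chrom.setdefault(p.chrom, []).append(p)
    for chrom in by_chrom:
        rows.extend(_predict_one_chrom(by_chrom[chrom], params))

    values = np.array([v for _, _, v in rows])
    ranks = rankdata(-values, method="average")
    return [
        FiringPrediction(
            promoter_id=p.id,
            chrom=p.chrom,
            pos=p.pos,
            state=p.state,
            l_used=l,
            ptrans=v,
            rank=float(r),
        )
        for (p, l, v), r in zip(rows, ranks)
    ]


def estimate_state_weights(
    promoters: Sequence[Promoter],
    signal: SignalTrack,
    params: LoopingParams | None = None,
) -> tuple[float | None, float | None, float | None]:
    """Estimate (b_g, b_ng, b_o) from a nascent-transcription track.

    Each promoter is scored by the value of the 3 kbp bin containing its
    position; weights are the per-state mean signals normalised so b_o = 1.
    When ``params`` is given, each promoter's signal is first divided by its
    loop factor (1 + c/l_genic) so the state weights are not confounded by
    proximity to genic promoters.  Empty classes yield None.
    """
    sums: dict[PromoterState, float] = {s: 0.0 for s in PromoterState}
    counts: dict[PromoterState, int] = {s: 0 for s in PromoterState}
    by_chrom: dict[str, list[Promoter]] = {}
    for p in promoters:
        by_chrom.setdefault(p.chrom, []).append(p)
    for chrom, plist in by_chrom.items():
        for i, p in enumerate(plist):
            v = signal.value_at(p.pos)
            if params is not None:
                l = nearest_genic_distance(plist, i)
                v /= 1.0 + (params.c / l if l else 0.0)
            sums[p.state] += v
            counts[p.state] += 1

    means = {
        s: (sums[s] / counts[s] if counts[s] else None) for s in PromoterState
    }
    b_o = means[PromoterState.OTHER]
    if b_o is None or b_o == 0:
        return (means[PromoterState.GENIC], means[PromoterState.NON_GENIC], b_o)
    norm = lambda m: (m / b_o if m is not None else None)
    return (norm(means[PromoterState.GENIC]), norm(means[PromoterState.NON_GENIC]), 1.0)


# ---------------------------------------------------------------------------
# Prediction table I/O
# ---------------------------------------------------------------------------

def write_predictions(preds: Sequence[FiringPrediction], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "promoter_id": [p.promoter_id for p in preds],
            "chrom": [p.chrom for p in preds],
            "pos": [p.pos for p in preds],
            "state": [p.state.value for p in preds],
            "l_used": [p.l_used if p.l_used is not None else "NA" for p in preds],
            "ptrans": [p.ptrans for p in preds],
            "rank": [p.rank for p in preds],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_predictions(path: str | Path) -> list[FiringPrediction]:
    df = pd.read_csv(path, sep="\t", dtype={"promoter_id": str, "chrom": str})
    out = []
    for r in df.itertuples():
        l = None if (isinstance(r.l_used, str) and r.l_used == "NA") else float(r.l_used)
        if l is not None and math.isnan(l):
            l = None
        out.append(
            FiringPrediction(
                promoter_id=str(r.promoter_id),
                chrom=r.chrom,
                pos=int(r.pos),
                state=PromoterState(r.state),
                l_used=l,
                ptrans=float(r.ptrans),
                rank=float(r.rank),
            )
        )
    return out
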
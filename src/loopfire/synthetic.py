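"""Synthetic chromosomes, promoter tracks and nascent-transcription signals.

Two generators are provided.  ``worked_example_fixture`` builds the canonical
five-promoter geometry (p, q, r, s, t at 0, 10, 40, 64, 84 kbp; q genic,
r/s/t non-genic, p other) used to exercise both formula variants end to end.
``synth_chromosome``/``synth_signal`` draw statistically realistic
chromosomes: promoter positions from a homogeneous Poisson process (default
mean spacing ~48 kbp, the density of active DHSs on human chromosome 14),
i.i.d. three-class state labels (default split 0.155/0.421/0.424, the
observed genic/non-genic/other proportions), and a signal track in which the
bin containing each promoter carries

    b_state * (1 + c / l_genic) * exp(eps),   eps ~ Normal(0, sigma^2),

i.e. the 3-state looping formula under multiplicative lognormal noise — a
stand-in for a GRO-seq profile with the model's statistical structure, not a
read-level simulation.

Generated promoters are kept at least one signal bin (3 kbp) apart so each
owns its evaluation bin; coincident draws are rejected and re-drawn.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .looping import LoopingParams, nearest_genic_distance
from .tracks import (
    DEFAULT_BIN_SIZE,
    GenomicInterval,
    Promoter,
    PromoterState,
    SignalTrack,
    write_bed,
    write_signal,
)

__all__ = [
    "SyntheticConfig",
    "worked_example_fixture",
    "worked_example_tracks",
    "synth_chromosome",
    "synth_signal",
    "emit_dataset",
]

#: Genic / non-genic / other split of the 2,226 active DHSs on HSA14 (HUVEC):
#: 344, 938 and 944 promoters respectively.
DEFAULT_PROPORTIONS = (344 / 2226, 938 / 2226, 944 / 2226)
#: Mean promoter spacing on HSA14: ~107 Mbp / 2,226 promoters.
DEFAULT_MEAN_SPACING = 48_000.0

_WORKED_POSITIONS_KBP = {"p": 0, "q": 10, "r": 40, "s": 64, "t": 84}
_WORKED_STATES = {
    "p": PromoterState.OTHER,
    "q": PromoterState.GENIC,
    "r": PromoterState.NON_GENIC,
    "s": PromoterState.NON_GENIC,
    "t": PromoterState.NON_GENIC,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for a synthetic chromosome."""

    chrom: str = "chrS"
    chrom_length: int = 48_000_000
    n_promoters: int | None = 1000
    mean_spacing: float = DEFAULT_MEAN_SPACING
    state_proportions: tuple[float, float, float] = DEFAULT_PROPORTIONS
    true_params: LoopingParams = field(default_factory=LoopingParams)
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.state_proportions) - 1.0) > 1e-9:
            raise ValueError("state_proportions must sum to 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def worked_example_fixture(chrom: str = "chrW") -> list[Promoter]:
    """The five-promoter worked-example geometry (positions in bp)."""
    return [
        Promoter(chrom=chrom, pos=1000 * _WORKED_POSITIONS_KBP[name],
                 state=_WORKED_STATES[name], id=name)
        for name in "pqrst"
    ]


def worked_example_tracks(
    peak_halfwidth: int = 300, chrom: str = "chrW"
) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
    """DHS peaks and HMM segments that classify back to the worked example.

    Each promoter becomes a DHS peak centred on its position; the HMM track
    carries a state-1 segment over the genic peak, state-4 segments over the
    non-genic peaks, and a state-7 segment over the *other* peak.
    """
    state_label = {
        PromoterState.GENIC: "1_Active_Promoter",
        PromoterState.NON_GENIC: "4_Strong_Enhancer",
        PromoterState.OTHER: "7_Weak_Enhancer",
    }
    dhs, hmm = [], []
    for p in worked_example_fixture(chrom):
        # keep the peak midpoint exactly on p.pos, even against the chromosome start
        start = max(0, p.pos - peak_halfwidth)
        end = max(2 * p.pos - start, p.pos + 1)
        dhs.append(GenomicInterval(chrom, start, end, p.id))
        hmm.append(GenomicInterval(chrom, start, end, state_label[p.state]))
    return dhs, hmm


def synth_chromosome(
    config: SyntheticConfig,
) -> tuple[list[Promoter], list[GenomicInterval], list[GenomicInterval]]:
    """Draw a synthetic chromosome: promoters plus matching DHS and HMM tracks.

    Positions come from a homogeneous Poisson process with the configured
    mean spacing (or exactly ``n_promoters`` uniform order statistics when a
    count is requested); draws closer than one signal bin to an accepted
    promoter are rejected and re-drawn.  States are i.i.d. from
    ``state_proportions``.  Deterministic per seed.
    """
    rng = np.random.default_rng(config.seed)
    min_sep = DEFAULT_BIN_SIZE
    length = config.chrom_length

    if config.n_promoters is not None:
        n = config.n_promoters
        if n < 2 or length < n * 2 * min_sep:
            raise ValueError("chromosome too short for the requested promoter count")
        positions: list[int] = []
        while len(positions) < n:
            draw = np.sort(rng.integers(min_sep, length - min_sep, size=n - len(positions)))
            for pos in draw:
                if all(abs(pos - q) >= min_sep for q in positions):
                    positions.append(int(pos))
        positions = sorted(positions)
    else:
        positions = []
        pos = 0.0
        while True:
            pos += rng.exponential(config.mean_spacing)
            if pos >= length - min_sep:
                break
            if not positions or pos - positions[-1] >= min_sep:
                positions.append(int(pos))
        if len(positions) < 2:
            raise ValueError("chromosome too short to hold >= 2 promoters")

    states = rng.choice(
        [PromoterState.GENIC, PromoterState.NON_GENIC, PromoterState.OTHER],
        size=len(positions),
        p=config.state_proportions,
    )
    state_label = {
        PromoterState.GENIC: "1_Active_Promoter",
        PromoterState.NON_GENIC: "4_Strong_Enhancer",
        PromoterState.OTHER: "7_Weak_Enhancer",
    }
    promoters, dhs, hmm = [], [], []
    for k, (pos, state) in enumerate(zip(positions, states)):
        pid = f"dhs{k:05d}"
        promoters.append(Promoter(chrom=config.chrom, pos=pos, state=state, id=pid))
        start, end = pos - 300, pos + 300
        dhs.append(GenomicInterval(config.chrom, start, end, pid))
        hmm.append(GenomicInterval(config.chrom, start, end, state_label[state]))
    return promoters, hmm, dhs


def synth_signal(
    promoters: list[Promoter],
    true_params: LoopingParams | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
    bin_size: int = DEFAULT_BIN_SIZE,
    chrom_length: int | None = None,
) -> SignalTrack:
    """Synthetic nascent-transcription track generated by the 3-state formula.

    The bin containing each promoter receives
    b_state·(1 + c/l_genic)·exp(ε) with ε ~ N(0, σ²) (loop term dropped when
    no other genic promoter exists); all other bins are zero.
    """
    if not promoters:
        raise ValueError("no promoters")
    params = true_params or LoopingParams()
    rng = np.random.default_rng(seed)
    chrom = promoters[0].chrom
    max_pos = max(p.pos for p in promoters)
    extent = chrom_length if chrom_length is not None else max_pos + bin_size
    values = np.zeros(int(np.ceil(extent / bin_size)))
    noise = rng.normal(0.0, noise_sigma, size=len(promoters)) if noise_sigma > 0 else np.zeros(len(promoters))
    for i, p in enumerate(promoters):
        l = nearest_genic_distance(promoters, i)
        base = params.b_for(p.state) * (1.0 + (params.c / l if l else 0.0))
        values[p.pos // bin_size] += base * np.exp(noise[i])
    return SignalTrack(chrom=chrom, bin_size=bin_size, values=values)


def toy_sim_promoters(
    n_beads: int = 200,
    n_tu: int = 10,
    state_counts: tuple[int, int, int] = (3, 4, 3),
    seed: int = 0,
    bead_bp: int = DEFAULT_BIN_SIZE,
    chrom: str = "chrS",
) -> list[Promoter]:
    """TU layout for a toy simulated chromosome (one promoter per chosen bead).

    ``n_tu`` distinct beads at least two beads apart are chosen at random and
    assigned a fixed genic/non-genic/other composition (shuffled per seed);
    each promoter sits at its bead centre, so formula distances and bead
    assignments agree exactly.
    """
    if sum(state_counts) != n_tu:
        raise ValueError("state_counts must sum to n_tu")
    rng = np.random.default_rng(seed)
    beads: list[int] = []
    while len(beads) < n_tu:
        cand = int(rng.integers(1, n_beads - 1))
        if all(abs(cand - b) >= 2 for b in beads):
            beads.append(cand)
    beads.sort()
    states = (
        [PromoterState.GENIC] * state_counts[0]
        + [PromoterState.NON_GENIC] * state_counts[1]
        + [PromoterState.OTHER] * state_counts[2]
    )
    rng.shuffle(states)  # type: ignore[arg-type]
    return [
        Promoter(chrom=chrom, pos=b * bead_bp + bead_bp // 2, state=s, id=f"tu{k:02d}")
        for k, (b, s) in enumerate(zip(beads, states))
    ]


def emit_dataset(config: SyntheticConfig, outdir: str | Path) -> dict:
    """Write dhs.bed, hmm.bed, signal.bedgraph and a manifest; return the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    promoters, hmm, dhs = synth_chromosome(config)
    track = synth_signal(
        promoters,
        config.true_params,
        config.noise_sigma,
        seed=config.seed + 1,
        chrom_length=config.chrom_length,
    )
    write_bed(dhs, outdir / "dhs.bed")
    write_bed(hmm, outdir / "hmm.bed")
    write_signal(track, outdir / "signal.bedgraph")
    manifest = {
        "chrom": config.chrom,
        "chrom_length": config.chrom_length,
        "n_promoters": len(promoters),
        "state_proportions": list(config.state_proportions),
        "true_params": {
            "c": config.true_params.c,
            "b_g": config.true_params.b_g,
            "b_ng": config.true_params.b_ng,
            "b_o": config.true_params.b_o,
        },
        "noise_sigma": config.noise_sigma,
        "seed": config.seed,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
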
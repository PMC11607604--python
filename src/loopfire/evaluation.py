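"""Rank-based comparison of predicted firing against a reference ranking.

The reference is typically nascent transcription (GRO-seq-like signal,
coarse-grained into 3 kbp bins) or residence-time estimates from polymer
simulation.  Agreement is quantified by Spearman's rank correlation (with the
large-n t approximation for p, or a seeded permutation test for small n), a
10x10 decile confusion matrix, and the decile agreement ratio — the number of
items falling in the same decile of both rankings divided by the chance
expectation n/10.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .tracks import Promoter, SignalTrack

__all__ = [
    "RankComparison",
    "spearman",
    "decile_confusion",
    "agreement_ratio",
    "reference_ranks",
    "compare_rankings",
    "plot_decile_heatmap",
]

#: Significance threshold applied to Spearman p-values in reports.
P_THRESHOLD = 1e-6


@dataclass(frozen=True)
class RankComparison:
    n: int
    spearman_rho: float
    p_value: float
    significant: bool  # p_value < P_THRESHOLD
    decile_matrix: np.ndarray  # 10x10 fractions, sums to 1
    agreement_ratio: float


def spearman(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "t",
    n_perm: int = 10_000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Spearman rho on tie-averaged ranks, with a p-value.

    ``method="t"`` uses the large-n Student-t approximation (scipy's default);
    ``method="permutation"`` runs a seeded two-sided permutation test,
    appropriate for small n.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if x.size < 3:
        raise ValueError("need at least 3 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: Spearman rho undefined")
    if method == "t":
        res = stats.spearmanr(x, y)
        return float(res.statistic), float(res.pvalue)
    if method == "permutation":
        rng = np.random.default_rng(seed)
        rho = float(stats.spearmanr(x, y).statistic)
        perm = np.empty(n_perm)
        for k in range(n_perm):
            perm[k] = stats.spearmanr(x, rng.permutation(y)).statistic
        p = (1 + np.sum(np.abs(perm) >= abs(rho) - 1e-12)) / (n_perm + 1)
        return rho, float(p)
    raise ValueError(f"unknown method {method!r}")


def _decile_labels(ranks: np.ndarray) -> np.ndarray:
    """Assign items to deciles 0..9 by rank position.

    Items are ordered by rank (best first; ties broken by stable index
    order); when n is not divisible by 10, earlier deciles receive the extra
    items.
    """
    n = ranks.size
    order = np.argsort(ranks, kind="stable")
    base, rem = divmod(n, 10)
    sizes = np.full(10, base)
    sizes[:rem] += 1
    labels = np.empty(n, dtype=int)
    labels[order] = np.repeat(np.arange(10), sizes)
    return labels


def decile_confusion(rank_a: Sequence[float], rank_b: Sequence[float]) -> np.ndarray:
    """10x10 matrix: entry (i, j) = fraction of items in decile i of ranking a
    and decile j of ranking b.  Entries sum to 1."""
    rank_a = np.asarray(rank_a, dtype=float)
    rank_b = np.asarray(rank_b, dtype=float)
    if rank_a.shape != rank_b.shape or rank_a.ndim != 1:
        raise ValueError("rankings must be equal-length 1-D arrays")
    n = rank_a.size
    if n < 10:
        raise ValueError("need at least 10 items for deciles")
    da, db = _decile_labels(rank_a), _decile_labels(rank_b)
    mat = np.zeros((10, 10))
    np.add.at(mat, (da, db), 1.0)
    return mat / n


def agreement_ratio(rank_a: Sequence[float], rank_b: Sequence[float]) -> float:
    """Count of items sharing a decile in both rankings over the chance
    expectation n/10.  10 for identical deciles, ~1 for independent rankings."""
    mat = decile_confusion(rank_a, rank_b)
    return float(10.0 * np.trace(mat))


def reference_ranks(signal: SignalTrack, promoters: Sequence[Promoter]) -> np.ndarray:
    """Reference ranking of promoters from a binned signal track.

    Each promoter is scored by the value of its containing bin; descending
    tie-averaged ranks are returned (rank 1 = strongest signal).  Promoters
    sharing a bin receive identical ranks; a promoter outside the track
    extent raises.
    """
    scores = np.array([signal.value_at(p.pos) for p in promoters])
    return stats.rankdata(-scores, method="average")


def compare_rankings(rank_a: Sequence[float], rank_b: Sequence[float]) -> RankComparison:
    """Full comparison report between two rankings of the same items."""
    rho, p = spearman(rank_a, rank_b)
    mat = decile_confusion(rank_a, rank_b)
    return RankComparison(
        n=len(rank_a),
        spearman_rho=rho,
        p_value=p,
        significant=bool(p < P_THRESHOLD),
        decile_matrix=mat,
        agreement_ratio=float(10.0 * np.trace(mat)),
    )


def plot_decile_heatmap(matrix: np.ndarray, path: str) -> None:
    """Save the decile confusion matrix as a heatmap (deciles, best first)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4))
    im = ax.imshow(matrix, origin="lower", cmap="viridis", vmin=0, vmax=0.1)
    ax.set_xlabel("reference decile")
    ax.set_ylabel("predicted decile")
    fig.colorbar(im, ax=ax, label="fraction of promoters")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
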
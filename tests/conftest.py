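"""Shared fixtures.

The Brownian-dynamics cross-validation study is expensive (minutes), so it
runs once per session and is shared by the polymer-behaviour tests and the
acceptance tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest
from scipy import stats

from loopfire.looping import LoopingParams, Mode, predict
from loopfire.polymer import ForceField, build_beads, simulate, toy_semiaxes
from loopfire.synthetic import toy_sim_promoters, worked_example_fixture

N_SEEDS = 8
N_BEADS = 200
N_TU = 10
N_TFPOLS = 10
# burn-in long enough for the chain's density profile to reach steady state
EQUIL_STEPS = 200_000
PROD_STEPS = 300_000
STRIDE = 500


@pytest.fixture
def worked_example():
    return worked_example_fixture()


@dataclass
class SimStudy:
    """Per-seed observables of the toy cross-validation study."""

    rho_three_state: list[float]  # sim residence vs 3-state formula
    rho_one_state: list[float]  # 1-state sim residence vs 3-state formula
    rho_shuffled_null: list[float]  # 3-state sim vs label-shuffled formula
    largest_cluster_attractive: list[float]  # 1-state (eps 7.1 everywhere)
    largest_cluster_control: list[float]  # eps = 0
    pooled_centroids: np.ndarray
    pooled_cluster_points: np.ndarray  # positions of clustered TF:pols
    semiaxes: np.ndarray


@pytest.fixture(scope="session")
def sim_study() -> SimStudy:
    """Run the toy 3-state / 1-state / non-attracting study over seeds."""
    ff3 = ForceField()
    ff1 = ff3.one_state()
    ff0 = ff3.non_attracting()

    rho3, rho1, rho_null = [], [], []
    lc_att, lc_ctrl = [], []
    centroids, cluster_points = [], []
    for seed in range(N_SEEDS):
        promoters = toy_sim_promoters(n_beads=N_BEADS, n_tu=N_TU, seed=seed)
        bead_map = build_beads(promoters, chrom_length=N_BEADS * 3000)
        formula = np.array(
            [p.ptrans for p in predict(promoters, LoopingParams(mode=Mode.THREE_STATE))]
        )

        common = dict(equil_steps=EQUIL_STEPS, prod_steps=PROD_STEPS, stride=STRIDE)
        r3 = simulate(bead_map, N_TFPOLS, forcefield=ff3, seed=100 + seed, **common)
        r1 = simulate(bead_map, N_TFPOLS, forcefield=ff1, seed=200 + seed, **common)
        r0 = simulate(bead_map, N_TFPOLS, forcefield=ff0, seed=300 + seed, **common)

        rho3.append(float(stats.spearmanr(r3.residence, formula).statistic))
        rho1.append(float(stats.spearmanr(r1.residence, formula).statistic))
        rng = np.random.default_rng(seed)
        rho_null.append(
            float(stats.spearmanr(r3.residence, rng.permutation(formula)).statistic)
        )
        lc_att.append(r1.mean_largest_cluster)
        lc_ctrl.append(r0.mean_largest_cluster)
        for r in (r3, r1):
            if r.cluster_centroids.size:
                centroids.append(r.cluster_centroids)
            if r.cluster_points.size:
                cluster_points.append(r.cluster_points)

    return SimStudy(
        rho_three_state=rho3,
        rho_one_state=rho1,
        rho_shuffled_null=rho_null,
        largest_cluster_attractive=lc_att,
        largest_cluster_control=lc_ctrl,
        pooled_centroids=np.vstack(centroids) if centroids else np.zeros((0, 3)),
        pooled_cluster_points=np.vstack(cluster_points) if cluster_points else np.zeros((0, 3)),
        semiaxes=toy_semiaxes(N_BEADS),
    )
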
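"""Brownian-dynamics bead-and-spring chromatin model with switching TF:pols.

A chromosome is a chain of beads (1 bead = 3 kbp, diameter σ = 30 nm, the
simulation length unit) confined in an ellipsoid.  Beads containing DHSs are
transcription units (TUs); TF:pol particles diffuse freely and, while in
their *active* state, are attracted to TU beads through a shifted, truncated
Lennard-Jones potential whose depth depends on the TU class (genic 7.1 kBT,
non-genic 4.4 kBT, other 3.5 kBT) and weakly (2.7 kBT) to acetylated
open-chromatin beads.  Everything else interacts purely repulsively
(Weeks–Chandler–Andersen).  Chain connectivity is a Kremer–Grest FENE
spring; a Kratky–Porod term sets the persistence length.  TF:pols switch
between active (binding) and inactive (non-binding) states at constant
rates, which lets clusters turn over.

Multivalent binding produces the bridging-induced attraction: bound TF:pols
spontaneously cluster into transcription-factory-like foci, and the fraction
of time a TU bead spends with an active TF:pol within the interaction range
is the simulation estimate of its firing probability (residence ptrans).

Reduced units: lengths in σ, energies in kBT, times in the Brownian time
τ = σ²γ/kBT with friction γ = 1.  The integrator is overdamped
(Euler–Maruyama) with a per-step displacement cap for stability against the
stiff excluded-volume core.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from numba import njit
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from .tracks import GenomicInterval, Promoter, PromoterState

__all__ = [
    "INERT",
    "ACETYLATED",
    "OTHER_TU",
    "NONGENIC_TU",
    "GENIC_TU",
    "BeadTypeMap",
    "ForceField",
    "SimState",
    "Trajectory",
    "SimResult",
    "FeneOverstretchError",
    "lj_norm",
    "lj_shifted",
    "build_beads",
    "toy_semiaxes",
    "init_state",
    "step",
    "switch_tfpols",
    "run",
    "simulate",
    "residence_ptrans",
    "detect_clusters",
    "largest_cluster_size",
    "peripheral_fraction",
    "sample_ellipsoid",
    "write_xyz",
    "write_trajectory_h5",
    "read_trajectory_h5",
]

SIGMA_NM = 30.0
BEAD_BP = 3000

#: Full-chromosome reference geometry: HSA14 bead count and territory semiaxes (σ).
PAPER_N_BEADS = 35_784
PAPER_SEMIAXES = np.array([22.24, 34.24, 41.80])

# Bead type codes
INERT, ACETYLATED, OTHER_TU, NONGENIC_TU, GENIC_TU = 0, 1, 2, 3, 4
_TYPE_NAMES = {INERT: "INERT", ACETYLATED: "ACETYLATED", OTHER_TU: "OTHER_TU",
               NONGENIC_TU: "NONGENIC_TU", GENIC_TU: "GENIC_TU"}

_WCA_CUT2 = 2.0 ** (1.0 / 3.0)  # squared WCA cutoff (2^{1/6} σ)²


class FeneOverstretchError(RuntimeError):
    """A FENE bond exceeded its maximum extension (time step too large)."""


# ---------------------------------------------------------------------------
# Force field and potentials
# ---------------------------------------------------------------------------

def lj_norm(rc: float) -> float:
    """Normalisation N making the truncated-shifted LJ depth equal −eps.

    N = 1 / (1 + 4[(σ/rc)^12 − (σ/rc)^6]) in reduced units (σ = 1).
    """
    if rc <= 1.0:
        raise ValueError("rc must exceed the bead diameter σ")
    s6 = (1.0 / rc) ** 6
    return 1.0 / (1.0 + 4.0 * (s6 * s6 - s6))


def lj_shifted(d, eps: float, rc: float = 1.8):
    """Truncated, shifted Lennard-Jones energy (kBT) at separation d (σ).

    U(d) = 4·eps·N·[(σ/d)^12 − (σ/d)^6 − (σ/rc)^12 + (σ/rc)^6] for d < rc and
    0 beyond; N makes the minimum exactly −eps (at d = 2^{1/6} σ).
    """
    N = lj_norm(rc)
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("d must be > 0")
    s6 = d ** -6.0
    s6c = rc ** -6.0
    u = 4.0 * eps * N * (s6 * s6 - s6 - (s6c * s6c - s6c))
    u = np.where(d < rc, u, 0.0)
    return float(u) if u.ndim == 0 else u


@dataclass(frozen=True)
class ForceField:
    """Interaction parameters (energies in kBT, lengths in σ).

    TU attraction strengths follow the 3-state model by default; use
    ``one_state()`` for the variant where every TU binds at the genic
    strength, or ``non_attracting()`` for the excluded-volume control.
    """

    eps_genic: float = 7.1
    eps_nongenic: float = 4.4
    eps_other: float = 3.5
    eps_acetyl: float = 2.7
    rc: float = 1.8
    wca_eps: float = 1.0
    fene_k: float = 30.0
    fene_r0: float = 1.6
    bend_k: float = 3.0  # Kratky-Porod stiffness ~ persistence length in σ
    confine_k: float = 10.0

    def __post_init__(self) -> None:
        if self.rc <= 1.0:
            raise ValueError("rc must exceed σ")
        for name in ("eps_genic", "eps_nongenic", "eps_other", "eps_acetyl"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def eps_by_type(self) -> np.ndarray:
        """Attraction strength indexed by bead type code (0 for inert)."""
        return np.array(
            [0.0, self.eps_acetyl, self.eps_other, self.eps_nongenic, self.eps_genic]
        )

    def one_state(self) -> "ForceField":
        """All TU classes bind at the genic strength (1-state model)."""
        return replace(
            self, eps_nongenic=self.eps_genic, eps_other=self.eps_genic
        )

    def non_attracting(self) -> "ForceField":
        """Excluded-volume control: no TU or acetyl attraction at all."""
        return replace(
            self, eps_genic=0.0, eps_nongenic=0.0, eps_other=0.0, eps_acetyl=0.0
        )


# ---------------------------------------------------------------------------
# Bead maps and geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BeadTypeMap:
    """Per-bead type codes at fixed genomic coarse-graining."""

    types: np.ndarray  # int8 codes
    bead_bp: int = BEAD_BP
    sigma_nm: float = SIGMA_NM

    @property
    def n_beads(self) -> int:
        return int(self.types.size)

    @property
    def tu_indices(self) -> np.ndarray:
        return np.flatnonzero(self.types >= OTHER_TU)

    def bead_interval(self, i: int, chrom: str = "chrS") -> GenomicInterval:
        return GenomicInterval(
            chrom, i * self.bead_bp, (i + 1) * self.bead_bp, _TYPE_NAMES[int(self.types[i])]
        )


def build_beads(
    promoters: Sequence[Promoter],
    acetyl_intervals: Sequence[GenomicInterval] = (),
    chrom_length: int | None = None,
) -> BeadTypeMap:
    """Coarse-grain a chromosome into typed beads (bead i = [3000i, 3000(i+1))).

    A bead containing one or more promoters becomes a TU bead whose type is
    the highest-precedence contained state (genic > non-genic > other);
    non-TU beads overlapping an acetylated (H3K27Ac) interval become
    ACETYLATED; everything else is INERT.
    """
    if chrom_length is None:
        last = max([p.pos for p in promoters] + [iv.end - 1 for iv in acetyl_intervals])
        chrom_length = last + 1
    if chrom_length <= 0:
        raise ValueError("chrom_length must be > 0")
    n = int(np.ceil(chrom_length / BEAD_BP))
    types = np.zeros(n, dtype=np.int8)
    code = {PromoterState.GENIC: GENIC_TU, PromoterState.NON_GENIC: NONGENIC_TU,
            PromoterState.OTHER: OTHER_TU}
    for p in promoters:
        b = p.pos // BEAD_BP
        types[b] = max(types[b], code[p.state])
    for iv in acetyl_intervals:
        b0, b1 = iv.start // BEAD_BP, min((iv.end - 1) // BEAD_BP, n - 1)
        for b in range(b0, b1 + 1):
            if types[b] == INERT:
                types[b] = ACETYLATED
    return BeadTypeMap(types=types)


def toy_semiaxes(n_beads: int) -> np.ndarray:
    """Ellipsoid semiaxes for a toy chromosome of ``n_beads`` beads.

    The full-chromosome territory is scaled isotropically so the bead volume
    fraction and aspect ratio match the reference geometry.
    """
    return PAPER_SEMIAXES * (n_beads / PAPER_N_BEADS) ** (1.0 / 3.0)


@dataclass
class SimState:
    """Instantaneous simulation state (positions in σ)."""

    beads: np.ndarray  # (n_beads, 3)
    tfpols: np.ndarray  # (n_tfpols, 3)
    active: np.ndarray  # (n_tfpols,) bool
    bead_types: np.ndarray  # int8 codes
    semiaxes: np.ndarray  # (3,)
    step_count: int = 0

    @property
    def n_beads(self) -> int:
        return int(self.beads.shape[0])

    @property
    def n_tfpols(self) -> int:
        return int(self.tfpols.shape[0])

    def copy(self) -> "SimState":
        return SimState(
            beads=self.beads.copy(),
            tfpols=self.tfpols.copy(),
            active=self.active.copy(),
            bead_types=self.bead_types.copy(),
            semiaxes=self.semiaxes.copy(),
            step_count=self.step_count,
        )


def sample_ellipsoid(n: int, semiaxes: np.ndarray, rng: np.random.Generator,
                     margin: float = 0.0) -> np.ndarray:
    """Uniform random points inside an ellipsoid (rejection-free, via the unit ball)."""
    u = rng.standard_normal((n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    r = rng.random(n) ** (1.0 / 3.0)
    return u * r[:, None] * (np.asarray(semiaxes) - margin)


def init_state(
    bead_map: BeadTypeMap,
    n_tfpols: int,
    semiaxes: np.ndarray | None = None,
    seed: int = 0,
    active_fraction: float = 0.5,
) -> SimState:
    """Self-avoiding random-walk chain inside the ellipsoid plus TF:pols.

    Candidate bead placements closer than 0.9σ to any earlier bead are
    rejected (up to a retry budget) so the start configuration carries no
    hard overlaps that could snap FENE bonds during the first steps.
    """
    n = bead_map.n_beads
    semiaxes = np.asarray(semiaxes if semiaxes is not None else toy_semiaxes(n), dtype=float)
    rng = np.random.default_rng(seed)
    beads = np.empty((n, 3))
    beads[0] = 0.0
    inner = semiaxes - 0.5
    for i in range(1, n):
        best, best_d = None, -1.0
        for _ in range(500):
            d = rng.standard_normal(3)
            cand = beads[i - 1] + d / np.linalg.norm(d)  # bond length 1σ
            if np.sum((cand / inner) ** 2) >= 1.0:
                continue
            dmin = float(np.min(np.linalg.norm(beads[:i] - cand, axis=1)))
            if dmin >= 0.9:
                best = cand
                break
            if dmin > best_d:
                best, best_d = cand, dmin
        if best is None:  # pathological geometry; restart from the centre
            best = beads[i - 1] * 0.5
        beads[i] = best
    tfpols = sample_ellipsoid(n_tfpols, semiaxes, rng, margin=0.5)
    # nudge TF:pols off any bead they happen to overlap
    for k in range(n_tfpols):
        for _ in range(200):
            if np.min(np.linalg.norm(beads - tfpols[k], axis=1)) >= 0.9:
                break
            tfpols[k] = sample_ellipsoid(1, semiaxes, rng, margin=0.5)[0]
    active = rng.random(n_tfpols) < active_fraction
    return SimState(
        beads=beads,
        tfpols=tfpols,
        active=active,
        bead_types=bead_map.types.copy(),
        semiaxes=semiaxes,
    )


# ---------------------------------------------------------------------------
# Numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _build_pairs(pos, cutoff):
    P = pos.shape[0]
    maxp = P * (P - 1) // 2
    pi = np.empty(maxp, np.int32)
    pj = np.empty(maxp, np.int32)
    c2 = cutoff * cutoff
    k = 0
    for i in range(P - 1):
        for j in range(i + 1, P):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            if dx * dx + dy * dy + dz * dz < c2:
                pi[k] = i
                pj[k] = j
                k += 1
    return pi[:k].copy(), pj[:k].copy()


@njit(cache=True)
def _forces(pos, n_beads, att_eps, active, pi, pj, rc, ljN, wca_eps,
            fene_k, fene_r0, bend_k, semiaxes, conf_k):
    P = pos.shape[0]
    f = np.zeros((P, 3))
    pe = 0.0
    rc2 = rc * rc
    s6c = rc ** -6.0
    shift = s6c * s6c - s6c
    r02 = fene_r0 * fene_r0

    # non-bonded pair interactions over the neighbour list
    for k in range(pi.shape[0]):
        i = pi[k]
        j = pj[k]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        d2 = dx * dx + dy * dy + dz * dz
        if d2 <= 1e-12:
            continue
        eps_att = 0.0
        if i < n_beads and j >= n_beads:
            if active[j - n_beads]:
                eps_att = att_eps[i]
        elif j < n_beads and i >= n_beads:
            if active[i - n_beads]:
                eps_att = att_eps[j]
        if eps_att > 0.0:
            if d2 < rc2:
                inv2 = 1.0 / d2
                s6 = inv2 * inv2 * inv2
                s12 = s6 * s6
                pe += 4.0 * eps_att * ljN * (s12 - s6 - shift)
                fmag = 24.0 * eps_att * ljN * (2.0 * s12 - s6) * inv2
                f[i, 0] += fmag * dx
                f[i, 1] += fmag * dy
                f[i, 2] += fmag * dz
                f[j, 0] -= fmag * dx
                f[j, 1] -= fmag * dy
                f[j, 2] -= fmag * dz
        else:
            if d2 < _WCA_CUT2:
                inv2 = 1.0 / d2
                s6 = inv2 * inv2 * inv2
                s12 = s6 * s6
                pe += 4.0 * wca_eps * (s12 - s6) + wca_eps
                fmag = 24.0 * wca_eps * (2.0 * s12 - s6) * inv2
                f[i, 0] += fmag * dx
                f[i, 1] += fmag * dy
                f[i, 2] += fmag * dz
                f[j, 0] -= fmag * dx
                f[j, 1] -= fmag * dy
                f[j, 2] -= fmag * dz

    # FENE springs along the chain
    for i in range(n_beads - 1):
        dx = pos[i + 1, 0] - pos[i, 0]
        dy = pos[i + 1, 1] - pos[i, 1]
        dz = pos[i + 1, 2] - pos[i, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= r02:
            return f, pe, i
        x = 1.0 - r2 / r02
        pe += -0.5 * fene_k * r02 * np.log(x)
        fmag = -fene_k / x  # attractive
        f[i + 1, 0] += fmag * dx
        f[i + 1, 1] += fmag * dy
        f[i + 1, 2] += fmag * dz
        f[i, 0] -= fmag * dx
        f[i, 1] -= fmag * dy
        f[i, 2] -= fmag * dz

    # Kratky-Porod bending over bead triplets
    if bend_k > 0.0:
        for i in range(n_beads - 2):
            b1x = pos[i + 1, 0] - pos[i, 0]
            b1y = pos[i + 1, 1] - pos[i, 1]
            b1z = pos[i + 1, 2] - pos[i, 2]
            b2x = pos[i + 2, 0] - pos[i + 1, 0]
            b2y = pos[i + 2, 1] - pos[i + 1, 1]
            b2z = pos[i + 2, 2] - pos[i + 1, 2]
            n1 = np.sqrt(b1x * b1x + b1y * b1y + b1z * b1z)
            n2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
            if n1 < 1e-12 or n2 < 1e-12:
                continue
            e1x, e1y, e1z = b1x / n1, b1y / n1, b1z / n1
            e2x, e2y, e2z = b2x / n2, b2y / n2, b2z / n2
            cth = e1x * e2x + e1y * e2y + e1z * e2z
            pe += bend_k * (1.0 - cth)
            # F = bend_k * d(cos)/dr
            gx_i = -(e2x - cth * e1x) / n1
            gy_i = -(e2y - cth * e1y) / n1
            gz_i = -(e2z - cth * e1z) / n1
            gx_k = (e1x - cth * e2x) / n2
            gy_k = (e1y - cth * e2y) / n2
            gz_k = (e1z - cth * e2z) / n2
            f[i, 0] += bend_k * gx_i
            f[i, 1] += bend_k * gy_i
            f[i, 2] += bend_k * gz_i
            f[i + 2, 0] += bend_k * gx_k
            f[i + 2, 1] += bend_k * gy_k
            f[i + 2, 2] += bend_k * gz_k
            f[i + 1, 0] -= bend_k * (gx_i + gx_k)
            f[i + 1, 1] -= bend_k * (gy_i + gy_k)
            f[i + 1, 2] -= bend_k * (gz_i + gz_k)

    # soft ellipsoidal confinement
    a2x = semiaxes[0] * semiaxes[0]
    a2y = semiaxes[1] * semiaxes[1]
    a2z = semiaxes[2] * semiaxes[2]
    for p in range(P):
        u = (pos[p, 0] * pos[p, 0] / a2x + pos[p, 1] * pos[p, 1] / a2y
             + pos[p, 2] * pos[p, 2] / a2z)
        if u > 1.0:
            pe += conf_k * (u - 1.0) * (u - 1.0)
            g = -4.0 * conf_k * (u - 1.0)
            f[p, 0] += g * pos[p, 0] / a2x
            f[p, 1] += g * pos[p, 1] / a2y
            f[p, 2] += g * pos[p, 2] / a2z

    return f, pe, -1


@njit(cache=True)
def _run_kernel(pos, n_beads, att_eps, active, semiaxes, rc, ljN, wca_eps,
                fene_k, fene_r0, bend_k, conf_k, n_steps, stride, dt, kT,
                friction, p_on, p_off, seed, rebuild_every, nl_cutoff, max_disp):
    np.random.seed(seed)
    P = pos.shape[0]
    M = P - n_beads
    n_frames = n_steps // stride if stride > 0 else 0
    traj = np.empty((n_frames, P, 3))
    act_traj = np.empty((n_frames, M), np.bool_)
    pe_traj = np.empty(n_frames)
    noise_scale = np.sqrt(2.0 * kT * dt / friction)
    frame = 0
    pi, pj = _build_pairs(pos, nl_cutoff)
    for s in range(n_steps):
        if s > 0 and s % rebuild_every == 0:
            pi, pj = _build_pairs(pos, nl_cutoff)
        f, pe, bad = _forces(pos, n_beads, att_eps, active, pi, pj, rc, ljN,
                             wca_eps, fene_k, fene_r0, bend_k, semiaxes, conf_k)
        if bad >= 0:
            return traj[:frame], act_traj[:frame], pe_traj[:frame], bad, s
        for p in range(P):
            dx = f[p, 0] * dt / friction + noise_scale * np.random.standard_normal()
            dy = f[p, 1] * dt / friction + noise_scale * np.random.standard_normal()
            dz = f[p, 2] * dt / friction + noise_scale * np.random.standard_normal()
            norm = np.sqrt(dx * dx + dy * dy + dz * dz)
            if norm > max_disp:
                sc = max_disp / norm
                dx *= sc
                dy *= sc
                dz *= sc
            pos[p, 0] += dx
            pos[p, 1] += dy
            pos[p, 2] += dz
        for m in range(M):
            if active[m]:
                if np.random.random() < p_off:
                    active[m] = False
            else:
                if np.random.random() < p_on:
                    active[m] = True
        if stride > 0 and (s + 1) % stride == 0:
            traj[frame] = pos
            act_traj[frame] = active
            pe_traj[frame] = pe
            frame += 1
    return traj, act_traj, pe_traj, -1, n_steps


# ---------------------------------------------------------------------------
# Integration API
# ---------------------------------------------------------------------------

#: Per-step displacement cap (σ); standard BD safeguard against the stiff core.
MAX_DISP = 0.1
#: Neighbour-list skin (σ) and rebuild interval (steps).
NL_SKIN = 0.5
NL_REBUILD = 5

#: Default TF:pol switching rate (1/τ): mean dwell 10 τ in each state.
DEFAULT_RATE = 0.1


def _eps_per_bead(state: SimState, ff: ForceField) -> np.ndarray:
    return ff.eps_by_type()[state.bead_types.astype(np.int64)]


def _check_rates(rate_on: float, rate_off: float, dt: float) -> None:
    if rate_on < 0 or rate_off < 0:
        raise ValueError("rates must be >= 0")
    if rate_on * dt > 1 or rate_off * dt > 1:
        raise ValueError("rate*dt > 1: switching probability exceeds 1 per step")


def run(
    state: SimState,
    forcefield: ForceField | None = None,
    n_steps: int = 100_000,
    stride: int = 500,
    dt: float = 1e-3,
    temperature: float = 1.0,
    friction: float = 1.0,
    rate_on: float = DEFAULT_RATE,
    rate_off: float = DEFAULT_RATE,
    seed: int = 0,
) -> "Trajectory":
    """Advance ``state`` in place for ``n_steps`` and sample every ``stride``.

    Deterministic given the seed and step schedule.  Raises
    FeneOverstretchError (naming the bond) if a chain spring exceeds its
    maximum extension — the signature of a too-large time step.
    """
    ff = forcefield or ForceField()
    if dt <= 0:
        raise ValueError("dt must be > 0")
    _check_rates(rate_on, rate_off, dt)
    att = _eps_per_bead(state, ff)
    stacked = np.ascontiguousarray(np.vstack([state.beads, state.tfpols]))
    active = state.active.astype(np.bool_).copy()
    traj, act, pe, bad, steps_done = _run_kernel(
        stacked, state.n_beads, att, active, state.semiaxes.astype(float),
        ff.rc, lj_norm(ff.rc), ff.wca_eps, ff.fene_k, ff.fene_r0, ff.bend_k,
        ff.confine_k, n_steps, stride, dt, temperature, friction,
        rate_on * dt, rate_off * dt, seed, NL_REBUILD,
        max(ff.rc, _WCA_CUT2 ** 0.5) + NL_SKIN, MAX_DISP,
    )
    if bad >= 0:
        raise FeneOverstretchError(
            f"FENE bond {bad}-{bad + 1} over-stretched at step "
            f"{state.step_count + steps_done}; reduce dt"
        )
    n = state.n_beads
    # the kernel advances `stacked` and `active` in place
    state.beads = stacked[:n].copy()
    state.tfpols = stacked[n:].copy()
    state.active = active
    state.step_count += steps_done
    return Trajectory(
        beads=traj[:, :n], tfpols=traj[:, n:], active=act, potential_energy=pe,
        bead_types=state.bead_types.copy(), semiaxes=state.semiaxes.copy(),
        dt=dt, stride=stride,
    )


def step(
    state: SimState,
    forcefield: ForceField | None = None,
    dt: float = 1e-3,
    friction: float = 1.0,
    temperature: float = 1.0,
    seed: int = 0,
) -> SimState:
    """One overdamped Langevin update of all particles; returns a new state."""
    new = state.copy()
    run(new, forcefield, n_steps=1, stride=0, dt=dt, temperature=temperature,
        friction=friction, rate_on=0.0, rate_off=0.0, seed=seed)
    return new


def switch_tfpols(
    state: SimState, rate_on: float, rate_off: float, dt: float, seed: int = 0
) -> SimState:
    """Flip each TF:pol's activity with probability rate·dt (independent, seeded)."""
    _check_rates(rate_on, rate_off, dt)
    rng = np.random.default_rng(seed)
    new = state.copy()
    u = rng.random(state.n_tfpols)
    flip = np.where(state.active, u < rate_off * dt, u < rate_on * dt)
    new.active = np.where(flip, ~state.active, state.active)
    return new


# ---------------------------------------------------------------------------
# Trajectory analysis
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Sampled frames of a run (positions in σ)."""

    beads: np.ndarray  # (F, n_beads, 3)
    tfpols: np.ndarray  # (F, n_tfpols, 3)
    active: np.ndarray  # (F, n_tfpols) bool
    potential_energy: np.ndarray  # (F,)
    bead_types: np.ndarray
    semiaxes: np.ndarray
    dt: float
    stride: int

    @property
    def n_frames(self) -> int:
        return int(self.beads.shape[0])

    @property
    def tu_indices(self) -> np.ndarray:
        return np.flatnonzero(self.bead_types >= OTHER_TU)


@dataclass
class SimResult:
    """Summary observables of one production run."""

    tu_indices: np.ndarray
    residence: np.ndarray  # per-TU fraction of frames with a bound active TF:pol
    mean_largest_cluster: float
    cluster_centroids: np.ndarray  # pooled over frames, (K, 3)
    cluster_points: np.ndarray  # positions of clustered TF:pols, pooled, (K2, 3)
    peripheral_fraction: float  # of pooled cluster centroids


def residence_ptrans(traj: Trajectory, rc: float = 1.8) -> np.ndarray:
    """Per-TU firing estimate: fraction of frames with >= 1 active TF:pol
    within the interaction range rc of the TU bead."""
    if traj.n_frames == 0:
        raise ValueError("trajectory holds no sampled frames")
    tu = traj.tu_indices
    bound = np.zeros((traj.n_frames, tu.size), dtype=bool)
    for f in range(traj.n_frames):
        act = traj.active[f]
        if not act.any():
            continue
        tp = traj.tfpols[f][act]
        d = np.linalg.norm(traj.beads[f][tu][:, None, :] - tp[None, :, :], axis=2)
        bound[f] = (d < rc).any(axis=1)
    return bound.mean(axis=0)


def detect_clusters(
    positions: np.ndarray, d_cl: float = 1.8
) -> tuple[list[np.ndarray], np.ndarray]:
    """Single-linkage clusters (size >= 2) of points under threshold d_cl.

    Returns (member index arrays, centroids); both empty when no pair of
    points is within d_cl.
    """
    positions = np.asarray(positions, dtype=float)
    m = positions.shape[0]
    if m < 2:
        return [], np.zeros((0, 3))
    adj = squareform(pdist(positions) < d_cl)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    clusters, centroids = [], []
    for c in range(n_comp):
        members = np.flatnonzero(labels == c)
        if members.size >= 2:
            clusters.append(members)
            centroids.append(positions[members].mean(axis=0))
    return clusters, (np.array(centroids) if centroids else np.zeros((0, 3)))


def largest_cluster_size(positions: np.ndarray, d_cl: float = 1.8) -> int:
    """Size of the largest single-linkage component (1 for isolated points, 0 if empty)."""
    m = np.asarray(positions).shape[0]
    if m == 0:
        return 0
    clusters, _ = detect_clusters(positions, d_cl)
    return max((c.size for c in clusters), default=1)


def peripheral_fraction(points: np.ndarray, semiaxes: np.ndarray) -> float:
    """Fraction of points in the outer half of the ellipsoid's volume.

    The inner half-volume is the similar ellipsoid with semiaxes scaled by
    2^{-1/3}; a point is peripheral when it lies outside that surface.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] == 0:
        return float("nan")
    inner = np.asarray(semiaxes) * 2.0 ** (-1.0 / 3.0)
    u = np.sum((points / inner) ** 2, axis=1)
    return float(np.mean(u > 1.0))


def simulate(
    bead_map: BeadTypeMap,
    n_tfpols: int,
    forcefield: ForceField | None = None,
    seed: int = 0,
    equil_steps: int = 50_000,
    prod_steps: int = 300_000,
    stride: int = 500,
    dt: float = 1e-3,
    semiaxes: np.ndarray | None = None,
    rate_on: float = DEFAULT_RATE,
    rate_off: float = DEFAULT_RATE,
    return_trajectory: bool = False,
) -> SimResult | tuple[SimResult, Trajectory]:
    """Equilibrate, run production, and summarise firing/clustering observables."""
    ff = forcefield or ForceField()
    state = init_state(bead_map, n_tfpols, semiaxes=semiaxes, seed=seed)
    run(state, ff, n_steps=equil_steps, stride=0, dt=dt,
        rate_on=rate_on, rate_off=rate_off, seed=seed + 1)
    traj = run(state, ff, n_steps=prod_steps, stride=stride, dt=dt,
               rate_on=rate_on, rate_off=rate_off, seed=seed + 2)

    residence = residence_ptrans(traj, rc=ff.rc)
    sizes, centroids, members = [], [], []
    for f in range(traj.n_frames):
        act_pos = traj.tfpols[f][traj.active[f]]
        sizes.append(largest_cluster_size(act_pos, d_cl=ff.rc))
        clusters, cents = detect_clusters(act_pos, d_cl=ff.rc)
        if cents.size:
            centroids.append(cents)
            members.append(np.vstack([act_pos[c] for c in clusters]))
    pooled = np.vstack(centroids) if centroids else np.zeros((0, 3))
    result = SimResult(
        tu_indices=traj.tu_indices,
        residence=residence,
        mean_largest_cluster=float(np.mean(sizes)) if sizes else 0.0,
        cluster_centroids=pooled,
        cluster_points=np.vstack(members) if members else np.zeros((0, 3)),
        peripheral_fraction=peripheral_fraction(pooled, traj.semiaxes)
        if pooled.size else float("nan"),
    )
    return (result, traj) if return_trajectory else result


def write_trajectory_h5(traj: Trajectory, path: str | Path) -> None:
    """Save sampled frames to an HDF5 container (positions in σ)."""
    import h5py

    with h5py.File(path, "w") as h5:
        for name in ("beads", "tfpols", "active", "potential_energy",
                     "bead_types", "semiaxes"):
            h5.create_dataset(name, data=getattr(traj, name))
        h5.attrs["dt"] = traj.dt
        h5.attrs["stride"] = traj.stride


def read_trajectory_h5(path: str | Path) -> Trajectory:
    import h5py

    with h5py.File(path, "r") as h5:
        return Trajectory(
            beads=h5["beads"][:], tfpols=h5["tfpols"][:],
            active=h5["active"][:].astype(bool),
            potential_energy=h5["potential_energy"][:],
            bead_types=h5["bead_types"][:], semiaxes=h5["semiaxes"][:],
            dt=float(h5.attrs["dt"]), stride=int(h5.attrs["stride"]),
        )


def write_xyz(traj: Trajectory, path: str | Path, element_bead: str = "C",
              element_tfpol: str = "O") -> None:
    """Write sampled frames as extended XYZ (positions in σ)."""
    n, m = traj.beads.shape[1], traj.tfpols.shape[1]
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{n + m}\n")
            fh.write(f"frame {f} step {(f + 1) * traj.stride}\n")
            for x, y, z in traj.beads[f]:
                fh.write(f"{element_bead} {x:.4f} {y:.4f} {z:.4f}\n")
            for x, y, z in traj.tfpols[f]:
                fh.write(f"{element_tfpol} {x:.4f} {y:.4f} {z:.4f}\n")
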
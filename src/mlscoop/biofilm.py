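"""Off-lattice agent-based biofilm of matrix producers and non-producers.

Cells live in 3D above a square grid of substrate anchor points (spacing
``D``).  They interact through a pseudo-force that is repulsive at short range
and attractive at long range, ``H/d^6 - G_avg/d^2`` with ``G_avg`` the mean of
the two cells' attraction constants; extracellular-matrix (ECM) producers —
the social phenotype — have a 100-fold larger attraction constant and divide
5-fold slower.  The baseline attraction constant is fixed by requiring zero
net force between two asocial cells at separation ``D``, giving
``G = H / D^4``.  Motion blends the normalised net-force direction with a
random unit vector, ``(1-F) u_force + F u_rand``, at fixed speed of one grid
spacing per step.  Division is logistic-Poisson per phenotype; death removes
Poisson-many cells from the predation interface, the topmost cell of each
substrate window.  ECM production is thus costly to the individual but keeps
its local group compact and away from the predation interface — the social
trait of this model.

Three protocols mirror the group-model experiments: steady state of
homogeneous colonies, seeding from a single founder cell, and fixation of a
single social mutant inside an asocial colony at steady state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Optional

import numpy as np
import pandas as pd

from . import _biofilm_core as core

__all__ = [
    "BiofilmParams",
    "BiofilmState",
    "anchor_grid",
    "pairwise_force",
    "substrate_force",
    "net_forces",
    "move_cells",
    "divide_cells",
    "predation_interface",
    "remove_cells",
    "run_steady_state",
    "run_seeding",
    "run_fixation",
]

Phenotype = Literal["social", "asocial"]


@dataclass(frozen=True)
class BiofilmParams:
    """Model constants; defaults are the headline parameter set.

    ``grid_n`` controls the substrate: ``grid_n x grid_n`` anchors spaced
    ``D`` apart, sized so the grid side is roughly twice the footprint of the
    largest colony (20 for the 500-cell capacity; reduced colonies in tests
    use proportionally smaller grids).
    """

    H: float = 1.0
    D: float = 1.0
    ecm_fold: float = 100.0
    F: float = 0.5
    r_asocial: float = math.log(2.0)
    social_slowdown: float = 5.0
    K_BF: int = 500
    dt: float = 0.01
    L: float = 0.1
    grid_n: int = 20
    speed_gridpoints: float = 1.0
    jitter: float = 1e-6
    division_jitter: float = 0.05
    substrate_uses_own_g: bool = False
    window_pad: int = 8

    @property
    def G_asocial(self) -> float:
        """Zero net pair force at separation D: H/D^6 = G/D^2 => G = H/D^4."""
        return self.H / self.D**4

    @property
    def G_social(self) -> float:
        return self.ecm_fold * self.G_asocial

    @property
    def r_social(self) -> float:
        return self.r_asocial / self.social_slowdown

    def G_of(self, social) -> float | np.ndarray:
        return np.where(np.asarray(social, bool), self.G_social, self.G_asocial)


@dataclass
class BiofilmState:
    """Cell positions (N, 3) and phenotype flags (True = social) at step t."""

    positions: np.ndarray
    social: np.ndarray
    t: int = 0

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, float))
        self.social = np.asarray(self.social, bool)

    @property
    def n(self) -> int:
        return len(self.positions)

    @property
    def n_social(self) -> int:
        return int(self.social.sum())


def anchor_grid(params: BiofilmParams) -> np.ndarray:
    """(grid_n^2, 2) anchor xy coordinates at z = 0, spacing D, origin corner."""
    g = np.arange(params.grid_n) * params.D
    xx, yy = np.meshgrid(g, g, indexing="ij")
    return np.column_stack([xx.ravel(), yy.ravel()]).astype(float)


def grid_center(params: BiofilmParams) -> np.ndarray:
    side = (params.grid_n - 1) * params.D
    return np.array([side / 2.0, side / 2.0])


def pairwise_force(
    p_pos: np.ndarray,
    q_pos: np.ndarray,
    p_social: bool,
    q_social: bool,
    params: BiofilmParams,
) -> np.ndarray:
    """Pseudo-force exerted on cell p by cell q (3-vector; positive along
    q->p is repulsion)."""
    disp = np.asarray(p_pos, float) - np.asarray(q_pos, float)
    d = np.linalg.norm(disp)
    if d == 0:
        raise ValueError("coincident cells: zero separation")
    G_avg = 0.5 * (float(params.G_of(p_social)) + float(params.G_of(q_social)))
    mag = params.H / d**6 - G_avg / d**2
    return mag * disp / d


def substrate_force(
    p_pos: np.ndarray, p_social: bool, params: BiofilmParams
) -> np.ndarray:
    """Net anchor pseudo-force on a cell, summed over all substrate anchors.

    Anchors use half the baseline attraction constant (``G/2`` in place of the
    pair average); with ``substrate_uses_own_g`` the cell's own phenotype
    constant is halved instead.
    """
    anchors = anchor_grid(params)
    a3 = np.column_stack([anchors, np.zeros(len(anchors))])
    disp = np.asarray(p_pos, float)[None, :] - a3
    d = np.linalg.norm(disp, axis=1)
    if np.any(d == 0):
        raise ValueError("cell coincides with an anchor")
    G_sub = float(params.G_of(p_social)) if params.substrate_uses_own_g else params.G_asocial
    mag = params.H / d**6 - (G_sub / 2.0) / d**2
    return (mag / d) @ disp


def net_forces(state: BiofilmState, params: BiofilmParams) -> np.ndarray:
    """(N, 3) net pseudo-forces: all cell pairs plus all anchors (vectorised)."""
    pos = state.positions
    G = np.asarray(params.G_of(state.social), float)
    disp = pos[:, None, :] - pos[None, :, :]
    d2 = np.sum(disp**2, axis=-1)
    np.fill_diagonal(d2, np.inf)
    d2 = np.maximum(d2, 1e-18)
    G_avg = 0.5 * (G[:, None] + G[None, :])
    coef = (params.H / d2**3 - G_avg / d2) / np.sqrt(d2)
    out = np.einsum("ij,ijk->ik", coef, disp)
    anchors = anchor_grid(params)
    a3 = np.column_stack([anchors, np.zeros(len(anchors))])
    dispA = pos[:, None, :] - a3[None, :, :]
    dA2 = np.maximum(np.sum(dispA**2, axis=-1), 1e-18)
    G_sub = np.where(state.social, params.G_social, params.G_asocial) \
        if params.substrate_uses_own_g else np.full(state.n, params.G_asocial)
    coefA = (params.H / dA2**3 - (G_sub[:, None] / 2.0) / dA2) / np.sqrt(dA2)
    out += np.einsum("ij,ijk->ik", coefA, dispA)
    return out


def move_cells(
    state: BiofilmState,
    params: BiofilmParams,
    rng: np.random.Generator,
    randomized: bool = True,
) -> BiofilmState:
    """One motion step: blend of force direction and a random unit vector,
    fixed step length, reflective substrate, uniqueness jitter.

    ``randomized=False`` reproduces the relaxation phase (F = 0): pure descent
    along the force direction, cells with zero net force stay put.
    """
    pos = state.positions.copy()
    f = net_forces(state, params)
    fn = np.linalg.norm(f, axis=1, keepdims=True)
    u_force = np.divide(f, fn, out=np.zeros_like(f), where=fn > 0)
    if randomized:
        r = rng.normal(size=pos.shape)
        r /= np.linalg.norm(r, axis=1, keepdims=True)
        blend = (1.0 - params.F) * u_force + params.F * r
        zero = np.linalg.norm(blend, axis=1) < 1e-12
        blend[zero] = r[zero]
    else:
        blend = u_force
    bn = np.linalg.norm(blend, axis=1, keepdims=True)
    unit = np.divide(blend, bn, out=np.zeros_like(blend), where=bn > 1e-12)
    pos += params.speed_gridpoints * params.D * unit
    pos[:, 2] = np.abs(pos[:, 2])
    pos += params.jitter * params.D * rng.uniform(-1, 1, size=pos.shape)
    pos[:, 2] = np.abs(pos[:, 2])
    return BiofilmState(pos, state.social.copy(), state.t + 1)


def divide_cells(
    state: BiofilmState, params: BiofilmParams, rng: np.random.Generator
) -> BiofilmState:
    """Logistic-Poisson division per phenotype: Poisson(n_ph r_ph (1 - N/K) dt)
    cells of each phenotype (capped at n_ph) duplicate with a small positional
    jitter."""
    pos, soc = state.positions, state.social
    new_pos, new_soc = [pos], [soc]
    for phen, r in ((False, params.r_asocial), (True, params.r_social)):
        idx = np.flatnonzero(soc == phen)
        lam = idx.size * r * max(0.0, 1.0 - state.n / params.K_BF) * params.dt
        if lam <= 0 or idx.size == 0:
            continue
        k = min(int(rng.poisson(lam)), idx.size)
        if k == 0:
            continue
        chosen = rng.choice(idx, size=k, replace=False)
        jit = params.division_jitter * params.D * rng.uniform(-1, 1, size=(k, 3))
        babies = pos[chosen] + jit
        babies[:, 2] = np.abs(babies[:, 2])
        new_pos.append(babies)
        new_soc.append(np.full(k, phen))
    return BiofilmState(
        np.vstack(new_pos), np.concatenate(new_soc), state.t
    )


def predation_interface(state: BiofilmState, params: BiofilmParams) -> np.ndarray:
    """Indices of the topmost cell in every occupied substrate window (window
    side = anchor spacing D)."""
    if state.n == 0:
        return np.array([], int)
    wx = np.floor(state.positions[:, 0] / params.D).astype(int)
    wy = np.floor(state.positions[:, 1] / params.D).astype(int)
    keys = wx * (2**20) + wy
    order = np.lexsort((state.positions[:, 2], keys))
    sorted_keys = keys[order]
    is_last = np.r_[sorted_keys[1:] != sorted_keys[:-1], True]
    return np.sort(order[is_last])


def remove_cells(
    state: BiofilmState, params: BiofilmParams, rng: np.random.Generator
) -> BiofilmState:
    """Poisson(m L dt) removals drawn uniformly from the predation interface
    (capped at the interface size m)."""
    iface = predation_interface(state, params)
    m = iface.size
    if m == 0:
        return state
    k = min(int(rng.poisson(m * params.L * params.dt)), m)
    if k == 0:
        return state
    victims = rng.choice(iface, size=k, replace=False)
    keep = np.ones(state.n, bool)
    keep[victims] = False
    return BiofilmState(state.positions[keep], state.social[keep], state.t)


def step(
    state: BiofilmState,
    params: BiofilmParams,
    rng: np.random.Generator,
    randomized: bool = True,
    division: bool = True,
    removal: bool = True,
) -> BiofilmState:
    """Reference full step (pure numpy): motion, division, removal."""
    state = move_cells(state, params, rng, randomized=randomized)
    if division:
        state = divide_cells(state, params, rng)
    if removal:
        state = remove_cells(state, params, rng)
    return state


# ---------------------------------------------------------------------------
# protocols (numba-accelerated)
# ---------------------------------------------------------------------------


def _capacity(params: BiofilmParams) -> int:
    return params.K_BF + 128


def _alloc(params: BiofilmParams, state: BiofilmState):
    cap = max(_capacity(params), state.n + 128)
    pos = np.zeros((cap, 3))
    soc = np.zeros(cap, np.int64)
    G = np.zeros(cap)
    pos[: state.n] = state.positions
    soc[: state.n] = state.social.astype(np.int64)
    G[: state.n] = params.G_of(state.social)
    return pos, soc, G


def _bins(params: BiofilmParams) -> int:
    return params.grid_n + 2 * params.window_pad


def _phase(pos, G, soc, n, params, steps, seed, *, do_random=True,
           do_division=True, do_removal=True, stop_mode=core.STOP_NONE,
           stop_n=0, record_every=0):
    n_rec = (steps // record_every + 2) if record_every > 0 else 2
    rec = np.zeros((n_rec, 4), np.int64)
    n, status, t, ri, m_sum = core.run_biofilm(
        pos, G, soc, n, steps, seed,
        np.ascontiguousarray(anchor_grid(params)),
        params.H, params.G_asocial, params.F,
        params.r_social, params.r_asocial, float(params.K_BF), params.dt,
        params.L, params.speed_gridpoints * params.D, params.jitter * params.D,
        params.division_jitter * params.D, params.window_pad, _bins(params),
        params.D,
        do_random, do_division, do_removal, stop_mode, stop_n, record_every,
        rec,
    )
    return n, status, t, rec[:ri], m_sum


def _seed_pair(seed: int, *key: int) -> tuple[int, np.random.Generator]:
    ss = np.random.SeedSequence(seed, spawn_key=tuple(key))
    core_seed = int(ss.generate_state(1, np.uint32)[0] & 0x7FFFFFFF)
    return core_seed, np.random.Generator(np.random.PCG64(ss.spawn(1)[0]))


def _init_colony(
    params: BiofilmParams, n: int, rng: np.random.Generator
) -> np.ndarray:
    """n cells uniform in a central square of width 5% of the substrate side,
    heights uniform in [0, D/2]."""
    side = (params.grid_n - 1) * params.D
    w = 0.05 * side
    c = grid_center(params)
    xy = rng.uniform(-w / 2, w / 2, size=(n, 2)) + c
    z = rng.uniform(0.0, 0.5 * params.D, size=(n, 1))
    return np.hstack([xy, z])


_STATUS = {core.BF_TIMEOUT: "timeout", core.BF_EXTINCT: "extinct",
           core.BF_SUCCESS: "success", core.BF_ASOCIAL_FIXED: "asocial_fixed"}


def _series(rec: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(rec, columns=["t", "n_social", "n_asocial", "interface"])


def run_steady_state(
    params: BiofilmParams,
    phenotype: Phenotype,
    seed: int,
    relax_steps: int = 1000,
    steps: int = 20000,
    record_every: int = 100,
) -> dict:
    """Homogeneous colony at capacity: relaxation (force descent only, no
    division/removal) followed by the full dynamics.  Returns the final state,
    the recorded size series and the mean interface fraction."""
    social = phenotype == "social"
    _, init_rng = _seed_pair(seed, 0)
    pos0 = _init_colony(params, params.K_BF, init_rng)
    state = BiofilmState(pos0, np.full(params.K_BF, social))
    pos, soc, G = _alloc(params, state)
    s1, _ = _seed_pair(seed, 1)
    n, _, _, _, _ = _phase(pos, G, soc, state.n, params, relax_steps, s1,
                           do_random=False, do_division=False, do_removal=False)
    s2, _ = _seed_pair(seed, 2)
    n, status, t, rec, m_sum = _phase(
        pos, G, soc, n, params, steps, s2, record_every=record_every
    )
    series = _series(rec)
    sizes = series[["n_social", "n_asocial"]].sum(axis=1)
    return dict(
        status=_STATUS[status],
        n_final=int(n),
        series=series,
        mean_interface_fraction=(
            float(m_sum / steps / max(sizes.mean(), 1.0)) if steps > 0 else np.nan
        ),
        state=BiofilmState(pos[:n].copy(), soc[:n].astype(bool), t),
    )


def run_seeding(
    params: BiofilmParams,
    phenotype: Phenotype,
    seed: int,
    stop_n: int = 300,
    max_steps: int = 200_000,
    record_every: int = 100,
) -> dict:
    """Colony propagation from a single founder anchored at the substrate
    centre; success once the population exceeds ``stop_n``, failure on
    extinction."""
    social = phenotype == "social"
    _, init_rng = _seed_pair(seed, 0)
    c = grid_center(params)
    pos0 = np.array([[c[0], c[1], 0.25 * params.D]])
    state = BiofilmState(pos0, np.array([social]))
    pos, soc, G = _alloc(params, state)
    s1, _ = _seed_pair(seed, 1)
    n, status, t, rec, _ = _phase(
        pos, G, soc, 1, params, max_steps, s1,
        stop_mode=core.STOP_SEEDING, stop_n=stop_n, record_every=record_every,
    )
    return dict(
        outcome="success" if status == core.BF_SUCCESS else "extinct",
        steps=int(t),
        n_final=int(n),
        series=_series(rec),
    )


def run_fixation(
    params: BiofilmParams,
    seed: int,
    base_state: Optional[BiofilmState] = None,
    steady_steps: int = 5000,
    neutral_mutant: bool = False,
    max_steps: int = 500_000,
    record_every: int = 200,
) -> dict:
    """Fate of a single social mutant in an asocial colony at steady state.

    ``base_state`` may carry a pre-computed asocial steady state (one is
    generated otherwise); one uniformly chosen cell is relabelled social and
    the dynamics run until the biofilm homogenises.  ``neutral_mutant`` keeps
    the mutant's division rate and attraction at asocial values (label-only
    mutation) — the control whose fixation probability must be ~1/N.
    """
    if base_state is None:
        ss = run_steady_state(params, "asocial", seed=cell_seed_of(seed, 100),
                              steps=steady_steps, record_every=0)
        base_state = ss["state"]
    _, rng = _seed_pair(seed, 3)
    state = BiofilmState(base_state.positions.copy(),
                         np.zeros(base_state.n, bool))
    mutant = int(rng.integers(0, state.n))
    state.social[mutant] = True
    pos, soc, G = _alloc(params, state)
    if neutral_mutant:
        G[mutant] = params.G_asocial
        eff = replace(params, ecm_fold=1.0, social_slowdown=1.0)
    else:
        eff = params
    s1, _ = _seed_pair(seed, 4)
    n, status, t, rec, _ = _phase(
        pos, G, soc, state.n, eff, max_steps, s1,
        stop_mode=core.STOP_FIXATION, record_every=record_every,
    )
    outcome = {core.BF_SUCCESS: "social_fixed",
               core.BF_ASOCIAL_FIXED: "asocial_fixed",
               core.BF_EXTINCT: "extinct",
               core.BF_TIMEOUT: "timeout"}[status]
    return dict(
        outcome=outcome,
        steps=int(t),
        n_final=int(n),
        n_initial=state.n,
        series=_series(rec),
    )


def cell_seed_of(seed: int, *key: int) -> int:
    ss = np.random.SeedSequence(seed, spawn_key=tuple(key))
    return int(ss.generate_state(1, np.uint32)[0] & 0x7FFFFFFF)
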
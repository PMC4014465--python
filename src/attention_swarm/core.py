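"""Agent dynamics: attention-field neighbour choice, attraction/repulsion
moves with stop-at-D rules, asynchronous sweeps and quasi-stationarity.

The model: P point agents live in the square [0, L]^2.  At each elementary
update a random agent draws a gaze direction uniformly on [0, 2*pi) and
searches for its nearest neighbour inside the angular attention field of
amplitude ``alpha`` bisected by the gaze.  If the neighbour is farther than
the ideal distance D (the stress-zone radius) the agent steps a distance
``v`` toward it, stopping exactly at distance D if the step would intrude
the stress zone; if closer than D it steps away, stopping at D if the step
would overshoot.  Direction noise of strength ``eta`` rotates the movement
direction by a uniform angle in [-eta*pi, eta*pi].  One time unit (sweep)
is P such updates.  The simulation is declared quasi-stationary after
``qs_window`` consecutive sweeps with no position change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional

import numpy as np

from . import _kernels
from ._kernels import DIST_TOL

__all__ = [
    "SimulationParams",
    "SwarmState",
    "StepOutcome",
    "Trajectory",
    "init_uniform",
    "sample_gaze",
    "sector_nearest_neighbour",
    "move_agent",
    "sweep",
    "run",
    "is_absorbing",
]

TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class SimulationParams:
    """All model constants and run controls.

    Defaults are the typical parameterisation used throughout: a group of
    91 individuals at density ~30 per unit area with stress-zone radius
    0.1 and speed 0.0112 length units per time unit.
    """

    P: int = 91
    L: float = 1.74
    D: float = 0.1
    v: float = 0.0112
    alpha: float = math.pi / 2  # attention-field amplitude, radians
    eta: float = 0.0  # noise strength in [0, 1]
    qs_window: int = 100
    max_sweeps: int = 50_000
    seed: int = 0
    selection: str = "replacement"  # or "permutation"

    def __post_init__(self) -> None:
        if self.P < 1:
            raise ValueError("P must be >= 1")
        if self.L <= 0 or self.D <= 0 or self.v <= 0:
            raise ValueError("L, D and v must be positive")
        if not (0.0 < self.alpha <= TWO_PI):
            raise ValueError("alpha must be in (0, 2*pi]")
        if not (0.0 <= self.eta <= 1.0):
            raise ValueError("eta must be in [0, 1]")
        if self.qs_window < 1:
            raise ValueError("qs_window must be >= 1")
        if self.selection not in ("replacement", "permutation"):
            raise ValueError("selection must be 'replacement' or 'permutation'")

    @property
    def density(self) -> float:
        return self.P / self.L**2

    def with_(self, **kwargs) -> "SimulationParams":
        """Copy with some fields replaced."""
        return replace(self, **kwargs)


@dataclass
class SwarmState:
    """Positions of the P agents at sweep ``t``."""

    positions: np.ndarray  # (P, 2) float64, inside [0, L]^2
    t: int = 0

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must have shape (P, 2)")

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    def copy(self) -> "SwarmState":
        return SwarmState(self.positions.copy(), self.t)


@dataclass(frozen=True)
class StepOutcome:
    agent_index: int
    moved: bool
    displacement_norm: float


@dataclass
class Trajectory:
    """Time-sampled states of one seeded run."""

    params: SimulationParams
    seed: int
    samples: List[SwarmState] = field(default_factory=list)
    converged: bool = False
    t_conv: Optional[int] = None

    @property
    def final(self) -> SwarmState:
        return self.samples[-1]

    @property
    def initial(self) -> SwarmState:
        return self.samples[0]


def init_uniform(params: SimulationParams, rng: np.random.Generator) -> SwarmState:
    """P i.i.d. uniform points in [0, L]^2 at t = 0.

    Duplicate points (a measure-zero accident) are re-drawn so that
    initial states always have distinct positions.
    """
    pos = rng.uniform(0.0, params.L, size=(params.P, 2))
    while len(np.unique(pos, axis=0)) < params.P:  # pragma: no cover
        pos = rng.uniform(0.0, params.L, size=(params.P, 2))
    return SwarmState(pos, t=0)


def sample_gaze(rng: np.random.Generator) -> float:
    """Gaze direction, uniform on [0, 2*pi)."""
    return float(rng.uniform(0.0, TWO_PI))


def sector_nearest_neighbour(
    state: SwarmState, i: int, gaze: float, alpha: float
) -> Optional[int]:
    """Nearest agent to ``i`` whose bearing lies in the closed attention
    sector ``[gaze - alpha/2, gaze + alpha/2]`` (mod 2*pi), or ``None`` if
    the sector is empty.  ``alpha = 2*pi`` gives the global nearest
    neighbour (Hamilton's rule)."""
    if not (0.0 < alpha <= TWO_PI):
        raise ValueError("alpha must be in (0, 2*pi]")
    if not (0 <= i < state.n):
        raise IndexError(f"agent index {i} out of range")
    j = _kernels.nearest_in_sector(state.positions, i, float(gaze), float(alpha))
    return None if j < 0 else int(j)


def move_agent(
    state: SwarmState,
    i: int,
    j: int,
    params: SimulationParams,
    rng: np.random.Generator,
) -> StepOutcome:
    """One attraction/repulsion update of agent ``i`` toward/away from its
    chosen neighbour ``j``, in place.

    The step length is ``v`` along the (noise-rotated) direction; the agent
    stops where its path crosses the circle of radius D around ``j`` and is
    clamped to the box.  A pair already at distance D does not move.
    """
    if i == j:
        raise ValueError("an agent cannot target itself")
    noise_u = float(rng.uniform(-1.0, 1.0))
    disp = _kernels.move_one(
        state.positions, i, j, params.L, params.D, params.v, params.eta, noise_u
    )
    return StepOutcome(agent_index=i, moved=disp > 0.0, displacement_norm=float(disp))


def sweep(
    state: SwarmState, params: SimulationParams, rng: np.random.Generator
) -> tuple[SwarmState, int]:
    """One time unit: P single-agent updates, each seeing the positions
    left by the previous ones.  Agent selection is uniform with replacement
    (or a random permutation if ``params.selection == 'permutation'``).
    Agents with an empty attention sector do not move.  Returns the state
    (mutated in place, ``t`` advanced by 1) and the count of moves."""
    P = state.n
    if params.selection == "permutation":
        order = rng.permutation(P).astype(np.int64)
    else:
        order = rng.integers(0, P, size=P, dtype=np.int64)
    gazes = rng.uniform(0.0, TWO_PI, size=P)
    noise_u = rng.uniform(-1.0, 1.0, size=P)
    moved = _kernels.sweep_kernel(
        state.positions,
        order,
        gazes,
        noise_u,
        params.L,
        params.D,
        params.v,
        params.alpha,
        params.eta,
    )
    state.t += 1
    return state, int(moved)


def run(
    params: SimulationParams,
    sample_every: int = 0,
    initial: Optional[SwarmState] = None,
) -> Trajectory:
    """Simulate until quasi-stationarity or ``max_sweeps``.

    Quasi-stationarity is declared after ``qs_window`` consecutive sweeps
    with zero moves; ``t_conv`` is the sweep of the last recorded movement
    (window completion time minus the window length).  States are sampled
    at t = 0, every ``sample_every`` sweeps (0 = only endpoints) and at the
    final sweep.  Non-convergence within ``max_sweeps`` is a reported
    outcome (``converged = False``), not an error.
    """
    rng = np.random.default_rng(params.seed)
    state = initial.copy() if initial is not None else init_uniform(params, rng)
    traj = Trajectory(params=params, seed=params.seed, samples=[state.copy()])
    quiet = 0
    while state.t < params.max_sweeps:
        _, moved = sweep(state, params, rng)
        quiet = quiet + 1 if moved == 0 else 0
        if sample_every and state.t % sample_every == 0:
            traj.samples.append(state.copy())
        if quiet >= params.qs_window:
            traj.converged = True
            traj.t_conv = state.t - params.qs_window
            break
    if not traj.samples or traj.samples[-1].t != state.t:
        traj.samples.append(state.copy())
    return traj


def movable_agents(state: SwarmState, params: SimulationParams, tol: float = 1e-9) -> np.ndarray:
    """Indices of agents that could move for *some* gaze direction.

    Exact geometric test of quiescence: agent i can move iff there exists a
    gaze for which the nearest neighbour inside the attention sector lies
    at a distance differing from D by more than ``tol``.  For each
    candidate target j (processed by increasing distance), the gazes that
    put j inside the sector form the arc ``bearing(j) +/- alpha/2``; j is
    selectable iff that arc is not fully covered by the arcs of strictly
    nearer agents.  An empty result on a quiescent state certifies it as a
    true absorbing state of the noiseless dynamics.
    """
    pos = state.positions
    P = state.n
    half = 0.5 * params.alpha
    out = []
    for i in range(P):
        d = pos - pos[i]
        dist = np.hypot(d[:, 0], d[:, 1])
        dist[i] = np.inf
        order = np.argsort(dist, kind="stable")
        bearing = np.arctan2(d[:, 1], d[:, 0])
        covered: list[tuple[float, float]] = []  # merged arcs on [0, 2*pi)
        k = 0
        movable = False
        while k < P - 1 and not movable:
            # group of (numerically) equidistant candidates: none blocks
            # another, and selecting any of them moves i the same distance
            grp = [order[k]]
            while (
                k + 1 < P - 1
                and dist[order[k + 1]] - dist[order[k]] <= 1e-12
            ):
                k += 1
                grp.append(order[k])
            k += 1
            for j in grp:
                if abs(dist[j] - params.D) > tol and not _arc_covered(
                    bearing[j] - half, bearing[j] + half, covered
                ):
                    movable = True
                    break
            for j in grp:
                covered = _arc_union(covered, bearing[j] - half, bearing[j] + half)
            if (
                len(covered) == 1
                and covered[0][0] <= 1e-15
                and covered[0][1] >= TWO_PI - 1e-15
            ):
                break  # whole circle covered: no farther agent selectable
        if movable:
            out.append(i)
    return np.array(out, dtype=int)


def _norm_arc(lo: float, hi: float) -> list[tuple[float, float]]:
    """Split an arc into non-wrapping intervals inside [0, 2*pi)."""
    if hi - lo >= TWO_PI:
        return [(0.0, TWO_PI)]
    lo %= TWO_PI
    hi %= TWO_PI
    if lo <= hi:
        return [(lo, hi)]
    return [(0.0, hi), (lo, TWO_PI)]


#: angular slack for arc coverage: windows narrower than this are treated
#: as closed (a gaze would hit them with probability ~1e-10 per draw, so
#: they are dynamically irrelevant and usually pure bearing roundoff)
_ANG_TOL = 1e-9


def _arc_union(covered: list, lo: float, hi: float) -> list:
    ivals = covered + _norm_arc(lo, hi)
    ivals.sort()
    merged = [ivals[0]]
    for a, b in ivals[1:]:
        if a <= merged[-1][1] + _ANG_TOL:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


def _arc_covered(lo: float, hi: float, covered: list) -> bool:
    for a, b in _norm_arc(lo, hi):
        done = False
        for ca, cb in covered:
            if ca <= a + _ANG_TOL and b <= cb + _ANG_TOL:
                done = True
                break
        if not done:
            return False
    return True


def is_absorbing(state: SwarmState, D: float, tol: float = 1e-9) -> bool:
    """True iff every topological-neighbour pair sits at distance D
    (within ``tol``): the configuration is a perfect triangular packing and
    an absorbing state of the noiseless dynamics.

    Topological neighbours are Delaunay-adjacent pairs; degenerate
    (e.g. collinear) configurations are reported as not absorbing.
    """
    from scipy.spatial import Delaunay, QhullError

    pos = state.positions
    if pos.shape[0] < 2:
        raise ValueError("need at least two agents")
    if pos.shape[0] == 2:
        return bool(abs(np.linalg.norm(pos[0] - pos[1]) - D) <= tol)
    try:
        tri = Delaunay(pos)
    except QhullError:
        return False
    edges = set()
    for simplex in tri.simplices:
        for a in range(3):
            e = (simplex[a], simplex[(a + 1) % 3])
            edges.add((min(e), max(e)))
    for a, b in edges:
        if abs(np.linalg.norm(pos[a] - pos[b]) - D) > tol:
            return False
    return True
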
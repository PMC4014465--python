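"""Replicate-averaged, seeded experiment protocols.

Four protocols: the attention-angle sweep (phase characterisation and
fluctuation peak), the speed sweep (optimal speed and the power-law growth
of convergence time with population), the noise sweep (order-disorder
transition) and the selfish-herd scenario (domain-of-danger shrinkage over
time).

Seeding: each replicate's seed derives from ``(seed0, grid value, replicate
index)`` through :class:`numpy.random.SeedSequence`, so re-ordering or
extending a grid never perturbs existing cells and every experiment is a
pure function of its arguments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import metrics
from .core import SimulationParams, SwarmState, Trajectory, run

__all__ = [
    "SweepResult",
    "HerdResult",
    "replicate_seed",
    "run_replicate",
    "sweep_alpha",
    "sweep_speed",
    "sweep_noise",
    "herd_scenario",
    "fit_power_law",
]

#: metric columns aggregated by every sweep
_METRIC_COLS = ["psi6", "T", "T_excl", "mean_area", "total_area", "n_clusters",
                "area_reduction"]


@dataclass
class SweepResult:
    """Aggregated outcome of one parameter sweep.

    ``records`` holds one row per replicate (grid value, replicate index,
    seed, metrics, convergence flag, t_conv); ``table`` one row per grid
    value with replicate means/standard deviations, the convergence
    probability and censored-run count.  ``info`` carries sweep-specific
    scalars (fluctuation-peak location, fitted exponents, ...).
    """

    parameter_name: str
    grid: np.ndarray
    replicates: int
    records: pd.DataFrame
    table: pd.DataFrame
    info: Dict[str, float] = field(default_factory=dict)


@dataclass
class HerdResult:
    """Time course of the normalised occupied area in the herd scenario."""

    times: np.ndarray
    normalized_area: np.ndarray  # A(t) / A(0)
    reduction_at_horizon: float  # mean-polygon-area reduction at t = horizon
    reduction_at_qs: Optional[float]  # same at quasi-stationarity (None if not reached)
    trajectory: Trajectory


def _value_key(value: float | int) -> int:
    """Stable 64-bit key for a grid value (bit pattern for floats)."""
    if isinstance(value, (int, np.integer)):
        return int(value)
    return int(np.float64(value).view(np.uint64))


def replicate_seed(seed0: int, value: float | int, rep: int) -> int:
    """Deterministic replicate seed from (seed0, grid value, replicate)."""
    ss = np.random.SeedSequence([int(seed0), _value_key(value), int(rep)])
    return int(ss.generate_state(1)[0] % (2**31))


def run_replicate(params: SimulationParams) -> Tuple[Trajectory, SwarmState, SwarmState]:
    traj = run(params)
    return traj, traj.initial, traj.final


def _metrics_row(
    initial: SwarmState, final: SwarmState, params: SimulationParams,
    rt_factor: float, link_factor: float,
) -> Dict[str, float]:
    rec = metrics.evaluate_state(
        final.positions, params.L, params.D, t=final.t,
        rt_factor=rt_factor, link_factor=link_factor,
    )
    red = metrics.area_reduction(
        initial.positions, final.positions, params.L,
        clip="hull", hull_pad=params.D / 2,
    )
    return {
        "psi6": rec.psi6,
        "T": rec.T,
        # exclusive count (focal individual not counted): the convention
        # under which the fragmented-phase plateau sits close to 2
        "T_excl": rec.T - 1.0,
        "mean_area": rec.mean_area,
        "total_area": rec.total_area,
        "n_clusters": rec.n_clusters,
        "area_reduction": red,
    }


def _aggregate(records: pd.DataFrame, by: List[str]) -> pd.DataFrame:
    rows = []
    for keys, grp in records.groupby(by, sort=False):
        keys = keys if isinstance(keys, tuple) else (keys,)
        row = dict(zip(by, keys))
        row["replicates"] = len(grp)
        row["n_converged"] = int(grp["converged"].sum())
        row["p_converged"] = grp["converged"].mean()
        conv = grp[grp["converged"]]
        row["mean_t_conv"] = conv["t_conv"].mean() if len(conv) else np.nan
        for col in _METRIC_COLS:
            if col in grp:
                row[f"{col}_mean"] = grp[col].mean()
                row[f"{col}_std"] = grp[col].std(ddof=0)
        rows.append(row)
    return pd.DataFrame(rows)


def _sweep_over(
    base: SimulationParams,
    parameter_name: str,
    grid: Sequence[float],
    replicates: int,
    seed0: int,
    rt_factor: float = 1.3,
    link_factor: float = 1.5,
) -> pd.DataFrame:
    """Run `replicates` seeded simulations per grid value of a single
    SimulationParams field and collect per-replicate final-state metrics."""
    rows = []
    for value in grid:
        for rep in range(replicates):
            seed = replicate_seed(seed0, value, rep)
            params = base.with_(**{parameter_name: value}, seed=seed)
            traj, initial, final = run_replicate(params)
            row = {
                parameter_name: value,
                "replicate": rep,
                "seed": seed,
                "converged": traj.converged,
                "t_conv": traj.t_conv if traj.converged else np.nan,
                "t_final": final.t,
            }
            row.update(_metrics_row(initial, final, params, rt_factor, link_factor))
            rows.append(row)
    return pd.DataFrame(rows)


def sweep_alpha(
    base: SimulationParams,
    alpha_grid: Sequence[float],
    replicates: int,
    seed0: int,
    rt_factor: float = 1.3,
    link_factor: float = 1.5,
) -> SweepResult:
    """Order parameters versus the attention-field amplitude.

    Each replicate runs to quasi-stationarity (or ``max_sweeps``; such
    censored runs contribute their final state and are flagged).  The
    fluctuation peak — the alpha maximising the replicate standard
    deviation of Psi6 and of T — locates the order-disorder phase
    boundary.
    """
    records = _sweep_over(base, "alpha", list(alpha_grid), replicates, seed0,
                          rt_factor, link_factor)
    table = _aggregate(records, ["alpha"])
    info = {
        "fluctuation_peak_alpha_psi6": float(table.loc[table["psi6_std"].idxmax(), "alpha"]),
        "fluctuation_peak_alpha_T": float(table.loc[table["T_std"].idxmax(), "alpha"]),
    }
    return SweepResult("alpha", np.asarray(list(alpha_grid), dtype=float),
                       replicates, records, table, info)


def sweep_speed(
    base: SimulationParams,
    v_grid: Sequence[float],
    P_list: Sequence[int],
    replicates: int,
    seed0: int,
) -> SweepResult:
    """Convergence time versus speed for several population sizes.

    Reports, per population, the speed minimising the mean convergence
    time (an interior optimum exists), and fits a power law
    ``t_conv ~ c * P**gamma`` across populations at each one's optimal
    speed.  Non-converged replicates are censored: counted and reported,
    never averaged into ``t_conv``.
    """
    rows = []
    for P in P_list:
        # constant density: the box scales with sqrt(P)
        L = base.L * math.sqrt(P / base.P)
        for v in v_grid:
            for rep in range(replicates):
                seed = replicate_seed(seed0, float(v) + 1e6 * P, rep)
                params = base.with_(P=int(P), L=L, v=float(v), seed=seed)
                traj = run(params)
                rows.append({
                    "P": int(P), "v": float(v), "replicate": rep, "seed": seed,
                    "converged": traj.converged,
                    "t_conv": traj.t_conv if traj.converged else np.nan,
                    "t_final": traj.final.t,
                })
    records = pd.DataFrame(rows)
    table = _aggregate(records, ["P", "v"])
    info: Dict[str, float] = {}
    opt_rows = []
    for P in P_list:
        sub = table[table["P"] == P]
        if sub["mean_t_conv"].notna().any():
            best = sub.loc[sub["mean_t_conv"].idxmin()]
            info[f"optimal_v_P{P}"] = float(best["v"])
            opt_rows.append((P, best["mean_t_conv"]))
    if len(opt_rows) >= 3:
        Ps, ts = zip(*opt_rows)
        gamma, gamma_se, logc = fit_power_law(np.array(Ps, float), np.array(ts, float))
        info["powerlaw_exponent"] = gamma
        info["powerlaw_exponent_se"] = gamma_se
        info["powerlaw_log_prefactor"] = logc
    return SweepResult("v", np.asarray(list(v_grid), dtype=float),
                       replicates, records, table, info)


def fit_power_law(x: np.ndarray, y: np.ndarray) -> Tuple[float, float, float]:
    """Least-squares fit of ``y = c * x**gamma`` on log-log axes.
    Returns (gamma, standard error of gamma, log c)."""
    from scipy.stats import linregress

    res = linregress(np.log(x), np.log(y))
    return float(res.slope), float(res.stderr), float(res.intercept)


def sweep_noise(
    base: SimulationParams,
    eta_grid: Sequence[float],
    horizon: int,
    replicates: int,
    seed0: int,
    rt_factor: float = 1.3,
    link_factor: float = 1.5,
) -> SweepResult:
    """Order parameters after a fixed number of sweeps versus the noise
    strength eta (no quasi-stationarity requirement).

    Also reports the empirical transition point: the eta at which the mean
    Psi6 first drops below 0.5 (linearly interpolated between grid points).
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    fixed = base.with_(max_sweeps=horizon, qs_window=horizon + 1)
    records = _sweep_over(fixed, "eta", list(eta_grid), replicates, seed0,
                          rt_factor, link_factor)
    table = _aggregate(records, ["eta"]).sort_values("eta").reset_index(drop=True)
    info: Dict[str, float] = {}
    psi = table["psi6_mean"].to_numpy()
    etas = table["eta"].to_numpy()
    below = np.nonzero(psi < 0.5)[0]
    if len(below) and below[0] > 0:
        k = below[0]
        e0, e1 = etas[k - 1], etas[k]
        p0, p1 = psi[k - 1], psi[k]
        info["transition_eta"] = float(e0 + (p0 - 0.5) * (e1 - e0) / (p0 - p1))
    elif len(below):
        info["transition_eta"] = float(etas[0])
    return SweepResult("eta", np.asarray(list(eta_grid), dtype=float),
                       replicates, records, table, info)


def herd_scenario(
    params: Optional[SimulationParams] = None,
    horizon: int = 600,
    seed: int = 0,
    record_every: int = 1,
) -> HerdResult:
    """Selfish-herd scenario: a group compacting from a uniform start,
    tracked by the total occupied Voronoi area A(t) normalised to A(0).

    Defaults follow the crab-swarm parameterisation: P = 90 individuals,
    D = mean inter-individual distance (0.1), v = mean attack speed
    (0.0112), in model units, with a small attention field.  A(t) is the
    area of the convex hull of the swarm inflated by D/2 (equal to the sum
    of the occupied-region Voronoi polygon areas).  Also reports the
    mean-polygon-area reduction at the horizon and, if reached, at
    quasi-stationarity.
    """
    if params is None:
        params = SimulationParams(P=90, alpha=math.pi / 2)
    params = params.with_(seed=seed, max_sweeps=max(horizon, params.max_sweeps))
    traj = run(params, sample_every=record_every)
    from shapely.geometry import MultiPoint

    def occupied_area(state: SwarmState) -> float:
        return MultiPoint(state.positions).convex_hull.buffer(params.D / 2).area

    samples = [s for s in traj.samples if s.t <= horizon]
    times = np.array([s.t for s in samples])
    areas = np.array([occupied_area(s) for s in samples])
    a0 = areas[0]
    horizon_state = samples[-1]
    red_h = metrics.area_reduction(
        traj.initial.positions, horizon_state.positions, params.L,
        clip="hull", hull_pad=params.D / 2,
    )
    red_qs = None
    if traj.converged:
        red_qs = metrics.area_reduction(
            traj.initial.positions, traj.final.positions, params.L,
            clip="hull", hull_pad=params.D / 2,
        )
    return HerdResult(
        times=times,
        normalized_area=areas / a0,
        reduction_at_horizon=float(red_h),
        reduction_at_qs=red_qs,
        trajectory=traj,
    )
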
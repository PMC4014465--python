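"""Trajectory / metrics CSV readers and writers, and flat config files.

Trajectory CSV layout: header ``t,agent_id,x,y``, one row per agent per
sampled sweep, coordinates serialised with full round-trip ``repr``
precision so write-then-read is lossless for doubles.  A JSON sidecar
(``<name>.meta.json``) carries the parameters, seed and convergence
summary of the run that produced the file.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Dict, Optional, Union

import numpy as np
import pandas as pd

from .core import SimulationParams, SwarmState, Trajectory

__all__ = [
    "TrajectoryParseError",
    "write_trajectory",
    "read_trajectory",
    "sidecar_path",
    "read_config",
    "params_from_mapping",
]

log = logging.getLogger("attention_swarm")


class TrajectoryParseError(ValueError):
    """Malformed trajectory file; the message names the offending line."""


def sidecar_path(path: Union[str, Path]) -> Path:
    path = Path(path)
    return path.with_name(path.stem + ".meta.json")


def write_trajectory(traj: Trajectory, path: Union[str, Path]) -> None:
    """Write the sampled states as CSV plus a JSON metadata sidecar."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("t,agent_id,x,y\n")
        for state in traj.samples:
            for a in range(state.n):
                x = float(state.positions[a, 0])
                y = float(state.positions[a, 1])
                fh.write(f"{state.t},{a},{x!r},{y!r}\n")
    meta = {
        "params": dataclasses.asdict(traj.params),
        "seed": traj.seed,
        "converged": traj.converged,
        "t_conv": traj.t_conv,
    }
    sidecar_path(path).write_text(json.dumps(meta, indent=1))
    log.info(
        "wrote trajectory %s: P=%d frames=%d converged=%s t_conv=%s",
        path, traj.samples[0].n, len(traj.samples), traj.converged, traj.t_conv,
    )


def read_trajectory(path: Union[str, Path]) -> Trajectory:
    """Read a trajectory CSV (and its sidecar, if present).

    Raises :class:`TrajectoryParseError` for an empty file, missing or
    unknown columns, non-numeric coordinates, or frames with inconsistent
    agent counts — always naming the offending line or frame.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or all(not ln.strip() for ln in lines):
        raise TrajectoryParseError(f"{path}: empty trajectory file")
    header = [c.strip() for c in lines[0].split(",")]
    if header != ["t", "agent_id", "x", "y"]:
        raise TrajectoryParseError(
            f"{path}:1: expected header 't,agent_id,x,y', got {lines[0]!r}"
        )
    frames: Dict[int, Dict[int, tuple]] = {}
    for ln_no, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 4:
            raise TrajectoryParseError(f"{path}:{ln_no}: expected 4 fields, got {len(parts)}")
        try:
            t = int(parts[0])
            a = int(parts[1])
            x = float(parts[2])
            y = float(parts[3])
        except ValueError:
            raise TrajectoryParseError(f"{path}:{ln_no}: non-numeric value in {line!r}") from None
        frames.setdefault(t, {})
        if a in frames[t]:
            raise TrajectoryParseError(f"{path}:{ln_no}: duplicate agent {a} in frame t={t}")
        frames[t][a] = (x, y)
    times = sorted(frames)
    counts = {t: len(frames[t]) for t in times}
    n = counts[times[0]]
    for t in times:
        if counts[t] != n:
            raise TrajectoryParseError(
                f"{path}: frame t={t} has {counts[t]} agents, expected {n}"
            )
    samples = []
    for t in times:
        if sorted(frames[t]) != list(range(n)):
            raise TrajectoryParseError(f"{path}: frame t={t} has non-contiguous agent ids")
        pos = np.array([frames[t][a] for a in range(n)])
        samples.append(SwarmState(pos, t=t))

    params: Optional[SimulationParams] = None
    seed = 0
    converged = False
    t_conv = None
    meta_file = sidecar_path(path)
    if meta_file.exists():
        meta = json.loads(meta_file.read_text())
        params = SimulationParams(**meta["params"])
        seed = meta.get("seed", 0)
        converged = meta.get("converged", False)
        t_conv = meta.get("t_conv")
    else:
        # minimal params consistent with the data (box inferred from extent)
        L = float(max(1.0, np.max([s.positions.max() for s in samples])))
        params = SimulationParams(P=n, L=L)
    return Trajectory(params=params, seed=seed, samples=samples,
                      converged=converged, t_conv=t_conv)


_PARAM_TYPES = {f.name: f.type for f in dataclasses.fields(SimulationParams)}


def params_from_mapping(mapping: Dict[str, str]) -> SimulationParams:
    """Build SimulationParams from string key-value pairs (config/CLI)."""
    kwargs = {}
    for key, raw in mapping.items():
        if key not in _PARAM_TYPES:
            raise ValueError(f"unknown parameter {key!r}")
        if key in ("P", "qs_window", "max_sweeps", "seed"):
            kwargs[key] = int(raw)
        elif key == "selection":
            kwargs[key] = str(raw)
        else:
            kwargs[key] = float(raw)
    return SimulationParams(**kwargs)


def read_config(path: Union[str, Path]) -> Dict[str, str]:
    """Flat ``key = value`` config file; '#' starts a comment."""
    out: Dict[str, str] = {}
    for ln_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        stripped = line.split("#", 1)[0].strip()
        if not stripped:
            continue
        if "=" not in stripped:
            raise ValueError(f"{path}:{ln_no}: expected 'key = value', got {line!r}")
        key, value = (s.strip() for s in stripped.split("=", 1))
        out[key] = value
    return out


def metrics_to_csv(records: pd.DataFrame, path: Union[str, Path]) -> None:
    records.to_csv(path, index=False)
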
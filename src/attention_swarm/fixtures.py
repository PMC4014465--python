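"""Analytic test configurations.

Each fixture carries its analytically forced expectations (lattice
geometry, shell counts), never simulation output, so metric code can be
validated against closed-form values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np

__all__ = [
    "Fixture",
    "make_triangular_lattice",
    "make_hexagon_motif",
    "make_isolated_pairs",
    "make_uniform_cloud",
]

SQRT3 = math.sqrt(3.0)


@dataclass(frozen=True)
class Fixture:
    name: str
    positions: np.ndarray
    expected: Dict[str, float] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.positions)


def make_triangular_lattice(
    spacing: float, shells: int, center: Tuple[float, float] = (0.0, 0.0)
) -> Fixture:
    """Hexagonal patch of the triangular lattice: a centre point plus
    ``shells`` complete shells, 1 + 3*shells*(shells+1) points in total.

    Expected values: interior Psi6 = 1, nearest-neighbour distance =
    spacing, interior Voronoi cell area = (sqrt(3)/2) * spacing**2.
    """
    if spacing <= 0 or shells < 1:
        raise ValueError("spacing must be positive and shells >= 1")
    a1 = np.array([1.0, 0.0]) * spacing
    a2 = np.array([0.5, SQRT3 / 2.0]) * spacing
    pts = []
    for q in range(-shells, shells + 1):
        for r in range(-shells, shells + 1):
            if abs(q + r) <= shells:  # hex-ball in axial coordinates
                pts.append(q * a1 + r * a2)
    pos = np.array(pts) + np.asarray(center, dtype=float)
    return Fixture(
        name=f"triangular_lattice_s{shells}",
        positions=pos,
        expected={
            "n_points": 1 + 3 * shells * (shells + 1),
            "psi6_interior": 1.0,
            "nn_distance": spacing,
            "interior_cell_area": (SQRT3 / 2.0) * spacing**2,
        },
    )


def make_hexagon_motif(
    spacing: float, center: Tuple[float, float] = (0.0, 0.0)
) -> Fixture:
    """A centre point with its 6 hexagon vertices (first point = centre).
    The centre has exactly 6 topological neighbours and psi6(centre) = 1."""
    ang = np.arange(6) * (math.pi / 3.0)
    ring = spacing * np.column_stack([np.cos(ang), np.sin(ang)])
    pos = np.vstack([[0.0, 0.0], ring]) + np.asarray(center, dtype=float)
    return Fixture(
        name="hexagon_motif",
        positions=pos,
        expected={"centre_neighbours": 6, "psi6_centre": 1.0},
    )


def make_isolated_pairs(
    n_pairs: int, spacing: float, separation: float
) -> Fixture:
    """Pairs at internal distance ``spacing``, laid out on a line with
    ``separation`` between pair centres.  With separation >> spacing the
    self-inclusive translational parameter at any radius in
    (spacing, separation - spacing) equals exactly 2."""
    if separation <= 2 * spacing:
        raise ValueError("separation must exceed 2*spacing to isolate pairs")
    pts = []
    for k in range(n_pairs):
        cx = k * separation
        pts.append([cx - spacing / 2.0, 0.0])
        pts.append([cx + spacing / 2.0, 0.0])
    return Fixture(
        name=f"isolated_pairs_{n_pairs}",
        positions=np.array(pts),
        expected={"T_self_inclusive": 2.0, "n_clusters": n_pairs},
    )


def make_uniform_cloud(n: int, L: float, seed: int) -> Fixture:
    """n i.i.d. uniform points in [0, L]^2 (seeded)."""
    rng = np.random.default_rng(seed)
    return Fixture(
        name=f"uniform_cloud_{n}",
        positions=rng.uniform(0.0, L, size=(n, 2)),
        expected={},
    )
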
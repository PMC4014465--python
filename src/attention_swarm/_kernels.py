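"""Numba-compiled inner loops of the agent dynamics.

These kernels operate on raw ``(P, 2)`` float64 position arrays and are
shared by the public single-agent operations and the full sweep, so there
is exactly one implementation of the movement rule.  All randomness is
drawn *outside* the kernels (numpy ``Generator``) and passed in as arrays,
which keeps runs bit-reproducible from a single integer seed.
"""

import math

import numpy as np
from numba import njit

TWO_PI = 2.0 * math.pi

#: Distances to the target within this tolerance of the ideal distance D
#: count as "already at D": the agent does not move.  Keeps configurations
#: that were clamped onto the D-circle (exact up to float rounding) from
#: jittering forever by sub-femtometre steps.
DIST_TOL = 1e-12


@njit(cache=True)
def nearest_in_sector(pos, i, gaze, alpha):
    """Index of the nearest agent to ``i`` with bearing within the closed
    sector ``gaze +/- alpha/2``, or -1 if the sector is empty.

    Ties (exactly equal distances) resolve to the lowest index; the sector
    boundary is closed.  With ``alpha == 2*pi`` this is the global nearest
    neighbour.
    """
    # bearing-within-half-angle test via the dot product with the gaze
    # direction: for deviation delta in [0, pi], delta <= alpha/2 iff
    # cos(delta) >= cos(alpha/2); rearranged to avoid sqrt/atan2 in the
    # O(P) inner loop.  The sector boundary is closed.
    half = 0.5 * alpha
    c = math.cos(half)
    gx = math.cos(gaze)
    gy = math.sin(gaze)
    xi = pos[i, 0]
    yi = pos[i, 1]
    best = -1
    best_d2 = np.inf
    for j in range(pos.shape[0]):
        if j == i:
            continue
        dx = pos[j, 0] - xi
        dy = pos[j, 1] - yi
        d2 = dx * dx + dy * dy
        if d2 >= best_d2 or d2 == 0.0:
            continue
        dot = dx * gx + dy * gy
        if c >= 0.0:
            inside = dot >= 0.0 and dot * dot >= c * c * d2
        else:
            inside = dot >= 0.0 or dot * dot <= c * c * d2
        if inside:
            best_d2 = d2
            best = j
    return best


@njit(cache=True)
def move_one(pos, i, j, L, D, v, eta, noise_u):
    """Update agent ``i`` relative to target ``j`` in place.

    Attraction when the pair distance d > D, repulsion when d < D, no move
    when d == D (within DIST_TOL).  The step has length ``v`` along the
    (possibly noise-rotated) ideal direction, but the agent stops where its
    path first crosses the circle of radius D around ``j``; the resulting
    position is clamped to the box [0, L]^2.  ``noise_u`` is a pre-drawn
    uniform variate on [-1, 1]; the rotation angle is ``noise_u * eta * pi``.

    Returns the displacement actually travelled (0.0 means no move).
    """
    xi = pos[i, 0]
    yi = pos[i, 1]
    dx = pos[j, 0] - xi
    dy = pos[j, 1] - yi
    d = math.sqrt(dx * dx + dy * dy)
    if abs(d - D) <= DIST_TOL or d == 0.0:
        return 0.0
    if d > D:
        ux = dx / d
        uy = dy / d
    else:
        ux = -dx / d
        uy = -dy / d
    if eta > 0.0:
        th = noise_u * eta * math.pi
        c = math.cos(th)
        s = math.sin(th)
        ux, uy = c * ux - s * uy, s * ux + c * uy

    t = v
    nx = xi + v * ux
    ny = yi + v * uy
    ndx = pos[j, 0] - nx
    ndy = pos[j, 1] - ny
    nd = math.sqrt(ndx * ndx + ndy * ndy)
    crossed = (d > D and nd < D) or (d < D and nd > D)
    if crossed:
        # first point along the path where |x + t*u - x_j| = D
        b = -(dx * ux + dy * uy)  # (x_i - x_j) . u
        disc = b * b - (d * d - D * D)
        if disc > 0.0:
            r = math.sqrt(disc)
            t1 = -b - r
            t2 = -b + r
            if 0.0 < t1 <= v:
                t = t1
            elif 0.0 < t2 <= v:
                t = t2
            nx = xi + t * ux
            ny = yi + t * uy

    if nx < 0.0:
        nx = 0.0
    elif nx > L:
        nx = L
    if ny < 0.0:
        ny = 0.0
    elif ny > L:
        ny = L

    ddx = nx - xi
    ddy = ny - yi
    disp = math.sqrt(ddx * ddx + ddy * ddy)
    if disp > 0.0:
        pos[i, 0] = nx
        pos[i, 1] = ny
    return disp


@njit(cache=True)
def sweep_kernel(pos, order, gazes, noise_u, L, D, v, alpha, eta):
    """One asynchronous sweep: ``len(order)`` single-agent updates, each
    seeing the positions left by the previous ones.  Returns the number of
    updates that produced an actual move."""
    moved = 0
    for k in range(order.shape[0]):
        i = order[k]
        j = nearest_in_sector(pos, i, gazes[k], alpha)
        if j >= 0:
            if move_one(pos, i, j, L, D, v, eta, noise_u[k]) > 0.0:
                moved += 1
    return moved
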
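"""Single-degree-of-freedom rigid folding of RFFQM crease patterns.

The driving angle ``rho`` is the fold angle (dihedral deviation from flat) of
the driving crease — the south spoke of the lower-left internal vertex, i.e.
the first internal crease of vertical line 0.  Every horizontal and vertical
crease polyline carries one fold-angle magnitude; the tangent half-angle
multiplier of each vertex transfers the magnitude between the lines through
it, so the whole fold-angle field is an analytic function of ``rho`` alone.

Signs follow the mountain/valley assignment: valley creases fold positive,
mountain creases negative.  The 3D embedding places panels rigidly by
breadth-first rotation about shared creases and is validated by loop-closure
residuals on all non-tree creases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pattern import CreasePattern

#: margin (degrees) kept between any fold angle and the flat-folded limit 180
FOLD_LIMIT_MARGIN_DEG = 0.5


class FoldLimitError(ValueError):
    """Requested driving angle exceeds the foldable range of the pattern."""


class EmbeddingError(RuntimeError):
    """Panel placement failed to close around an interior vertex."""


@dataclass
class FoldAngleField:
    """Signed fold angles (degrees) for every edge of a pattern.

    ``gamma[e]`` is positive on valley creases, negative on mountain creases
    and zero on boundary edges.  ``t_h[j]`` / ``t_v[i]`` are the tangent
    half-angle magnitudes of the horizontal / vertical crease lines.
    """

    rho: float
    gamma: np.ndarray  # (E,) signed degrees
    t_h: np.ndarray  # (n,)
    t_v: np.ndarray  # (n,)
    loop_residual: float  # degrees, multiplier-consistency residual


@dataclass
class FoldedState:
    """Rigid 3D embedding of a pattern at one driving angle."""

    coords: np.ndarray  # (V, 3)
    rho: float
    face_normals: np.ndarray  # (F, 3) unit vectors
    closure_residual: float = 0.0  # worst non-tree crease mismatch, pattern units


def line_magnitudes(pattern: CreasePattern, rho: float):
    """Tangent half-angle fold magnitude of every crease line at ``rho``.

    Returns ``(t_h, t_v)``.  The driving vertical line 0 folds by ``rho``;
    the lower-left vertex multiplier maps it to horizontal line 0 and the
    rank-1 multiplier field propagates to all remaining lines.
    """
    t = np.tan(np.radians(rho) / 2.0)
    mu = np.abs(pattern.mu)
    t_h = t / mu[:, 0]
    t_v = t * mu[0, :] / mu[0, 0]
    return t_h, t_v


def rho_max(pattern: CreasePattern, margin: float = FOLD_LIMIT_MARGIN_DEG) -> float:
    """Largest admissible driving angle, degrees.

    Found by bisection on the first fold angle to reach ``180 - margin``.
    For multiplier magnitudes above one some line always folds faster than
    the driving crease, so the limit is strictly below 180.
    """
    from scipy.optimize import brentq

    limit = 180.0 - margin

    def worst(rho):
        t_h, t_v = line_magnitudes(pattern, rho)
        return np.degrees(2.0 * np.arctan(max(t_h.max(), t_v.max()))) - limit

    if worst(limit) <= 0.0:
        return limit
    return float(brentq(worst, 0.0, limit, xtol=1e-10))


def propagate_fold_angles(pattern: CreasePattern, rho: float) -> FoldAngleField:
    """Fold angles of every crease at driving angle ``rho`` (degrees).

    The per-line magnitudes follow from the tangent half-angle transfer at
    the flat-foldable degree-4 vertices; signs come from the mountain/valley
    assignment.  The multiplier-consistency residual over all vertices is
    reported as ``loop_residual`` (degrees) and must vanish for a valid
    rank-1 multiplier field.
    """
    if rho < 0:
        raise FoldLimitError("rho must be >= 0")
    lim = rho_max(pattern)
    if rho > lim:
        raise FoldLimitError(f"rho={rho} exceeds rho_max={lim:.6f}")
    t_h, t_v = line_magnitudes(pattern, rho)

    # loop-closure / path-independence residual: the magnitude reaching each
    # vertex along its row must match the one along its column.
    mu = np.abs(pattern.mu)
    res = 0.0
    for j in range(pattern.grid_size):
        for i in range(pattern.grid_size):
            a = 2.0 * np.arctan(t_v[i])
            b = 2.0 * np.arctan(mu[j, i] * t_h[j])
            res = max(res, abs(np.degrees(a - b)))

    lines = pattern.edge_line()
    gamma = np.zeros(len(pattern.edges))
    for e, line in enumerate(lines):
        if line is None:
            continue
        kind, idx = line
        mag = np.degrees(2.0 * np.arctan(t_h[idx] if kind == "h" else t_v[idx]))
        gamma[e] = mag if pattern.assignment[e] == "V" else -mag
    return FoldAngleField(rho=rho, gamma=gamma, t_h=t_h, t_v=t_v, loop_residual=res)


def _rotation(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    x, y, z = axis
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    C = 1.0 - c
    return np.array(
        [
            [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
            [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
            [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
        ]
    )


def _face_adjacency(pattern: CreasePattern):
    """Map each internal crease edge index to its two adjacent faces."""
    edge_id = {frozenset(map(int, e)): k for k, e in enumerate(pattern.edges)}
    adj = {}
    for f, quad in enumerate(pattern.faces):
        for a, b in zip(quad, np.roll(quad, -1)):
            k = edge_id[frozenset((int(a), int(b)))]
            adj.setdefault(k, []).append(f)
    return {k: fs for k, fs in adj.items() if len(fs) == 2}


def embed_folded_state(
    pattern: CreasePattern,
    angles: FoldAngleField,
    anchor_face: int = 0,
    closure_tol: float = 1e-7,
) -> FoldedState:
    """Rigidly place all panels in 3D for the given fold-angle field.

    The anchor panel (lower-left by default) stays in the ``z = 0`` plane;
    panels are visited breadth-first, each rotated about the shared crease by
    its signed fold angle (valley folds lift the moving panel towards
    ``+z``).  Loop closure is checked on every non-tree crease; a residual
    above ``closure_tol`` (relative to the pattern diameter) raises
    :class:`EmbeddingError`.
    """
    flat = np.hstack([pattern.vertices, np.zeros((len(pattern.vertices), 1))])
    adj = _face_adjacency(pattern)
    nF = len(pattern.faces)

    # per-face affine transform p -> R p + o
    R = [None] * nF
    o = [None] * nF
    R[anchor_face] = np.eye(3)
    o[anchor_face] = np.zeros(3)

    from collections import deque

    centroids = {f: pattern.vertices[pattern.faces[f]].mean(axis=0) for f in range(nF)}
    queue = deque([anchor_face])
    order = []
    visited = {anchor_face}
    tree_crossings = []  # (edge, from_face, to_face)
    extra = []
    seen_edges = set()
    while queue:
        f = queue.popleft()
        order.append(f)
        for k, fs in adj.items():
            if f not in fs or k in seen_edges:
                continue
            g = fs[0] if fs[1] == f else fs[1]
            seen_edges.add(k)
            if g in visited:
                extra.append((k, f, g))
            else:
                visited.add(g)
                tree_crossings.append((k, f, g))
                queue.append(g)

    # deterministic BFS: process tree crossings in discovery order
    for k, f, g in tree_crossings:
        a, b = map(int, pattern.edges[k])
        pa, pb = pattern.vertices[a], pattern.vertices[b]
        # orient A->B so that face g lies to the left in the flat pattern
        d, c = pb - pa, centroids[g] - pa
        left = d[0] * c[1] - d[1] * c[0]
        if left < 0:
            a, b = b, a
            pa, pb = pb, pa
        gam = np.radians(angles.gamma[k])
        A3 = R[f] @ np.array([pa[0], pa[1], 0.0]) + o[f]
        B3 = R[f] @ np.array([pb[0], pb[1], 0.0]) + o[f]
        rot = _rotation(B3 - A3, gam)
        R[g] = rot @ R[f]
        o[g] = rot @ (o[f] - A3) + A3

    diameter = np.ptp(pattern.vertices, axis=0).max()
    worst = 0.0
    for k, f, g in extra:
        # consistency of the two placements of the shared crease endpoints
        a, b = map(int, pattern.edges[k])
        for v in (a, b):
            p = flat[v]
            d = np.linalg.norm((R[f] @ p + o[f]) - (R[g] @ p + o[g]))
            worst = max(worst, d)
    if worst > closure_tol * diameter:
        raise EmbeddingError(f"loop closure failed: worst residual {worst:.3e}")

    coords = np.zeros((len(flat), 3))
    counts = np.zeros(len(flat))
    for f in range(nF):
        for v in pattern.faces[f]:
            coords[v] += R[f] @ flat[v] + o[f]
            counts[v] += 1
    coords /= counts[:, None]

    normals = np.zeros((nF, 3))
    for f, quad in enumerate(pattern.faces):
        q = coords[quad]
        nvec = np.cross(q[2] - q[0], q[3] - q[1])
        normals[f] = nvec / np.linalg.norm(nvec)
    return FoldedState(
        coords=coords,
        rho=angles.rho,
        face_normals=normals,
        closure_residual=worst,
    )


def fold_state(pattern: CreasePattern, rho: float) -> FoldedState:
    """Convenience: propagate fold angles and embed in one call."""
    return embed_folded_state(pattern, propagate_fold_angles(pattern, rho))


def fold_sweep(pattern: CreasePattern, rhos) -> list:
    """One folded state per driving angle, in the given order."""
    return [fold_state(pattern, float(r)) for r in rhos]


def facet_dihedrals(state: FoldedState, pattern: CreasePattern) -> np.ndarray:
    """Per-internal-crease dihedral deviation from coplanarity, degrees.

    Computed as the angle between adjacent panel normals; zero when flat and
    equal to the magnitude of the crease's fold angle.
    """
    adj = _face_adjacency(pattern)
    out = np.zeros(len(pattern.edges))
    for k, (f, g) in adj.items():
        c = float(np.clip(np.dot(state.face_normals[f], state.face_normals[g]), -1, 1))
        out[k] = np.degrees(np.arccos(c))
    return out


def default_driving_angles(n_states: int = 8) -> np.ndarray:
    """The design folding schedule: ``{5, 10, ..., 5 * n_states}`` degrees."""
    return 5.0 * np.arange(1, n_states + 1)
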
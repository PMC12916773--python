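"""Rigidly and flat-foldable quadrilateral-mesh (RFFQM) crease patterns.

A crease pattern on an ``n x n`` grid of internal degree-4 vertices (default
``n = 5``) is generated from an L-shaped motif: the bottom row and left column
of internal vertices carry two free sector angles each (the other two follow
from Kawasaki's condition), together with the crease lengths along the bottom
row and left column and four boundary spokes.  The remaining interior geometry
is *marched* from the motif using the panel-compatibility structure of rigidly
flat-foldable quad meshes: every internal vertex carries a fold-angle
multiplier ``mu`` (the ratio of tangent half fold angles of its vertical and
horizontal creases), and single-degree-of-freedom rigid foldability forces the
multiplier field to be a rank-1 outer product of its first row and column.

Conventions
-----------
* Internal vertices are indexed ``(i, j)`` with column ``i`` and row ``j``
  counted from the lower-left corner.
* At each internal vertex the four sector angles are stored in the cyclic
  counter-clockwise order starting from the crease pointing to the west
  neighbour: ``(theta_WS, theta_SE, theta_EN, theta_NW)``.
* The free pair of a motif vertex is ``(alpha1, alpha2)`` and completes to
  ``(alpha1, alpha2, 180 - alpha1, 180 - alpha2)``.  Vertices in odd rows
  (``j % 2 == 1``) are mirrored, i.e. their free pair is applied as
  ``(alpha2, alpha1, ...)``, matching the row-wise alternation of the zigzag
  lean; with this convention a uniform motif reproduces the periodic
  Miura-ori exactly.
* The fold-angle multiplier of a vertex with ``p = theta_EN``, ``q = theta_NW``
  is ``mu = -sin((p + q)/2) / sin((q - p)/2)``; it relates tangent half fold
  angles of the vertical and horizontal crease lines through the vertex.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

#: feasibility margin for sector angles, degrees: angles must lie in
#: (ANGLE_MARGIN_DEG, 180 - ANGLE_MARGIN_DEG) to keep the kinematics stable.
ANGLE_MARGIN_DEG = 0.5

FAILURE_REASONS = (
    "angle-out-of-range",
    "kawasaki-violation",
    "negative-length",
    "crease-intersection",
    "marching-divergence",
)


class DegenerateVertexError(ValueError):
    """A completed degree-4 vertex has collinear creases (singular kinematics)."""


class InfeasiblePatternError(ValueError):
    """The motif cannot be marched into a valid crease pattern."""

    def __init__(self, reason: str, detail: str = ""):
        if reason not in FAILURE_REASONS:
            raise ValueError(f"unknown failure reason {reason!r}")
        self.reason = reason
        super().__init__(f"{reason}: {detail}" if detail else reason)


@dataclass(frozen=True)
class PatternDiagnostics:
    feasible: bool
    failure_reason: str | None = None
    detail: str = ""

    def __post_init__(self):
        if self.feasible == (self.failure_reason is not None):
            raise ValueError("feasible must be False iff a failure_reason is set")


@dataclass
class MotifParameters:
    """The free design variables of the L-shaped motif.

    ``free_angles`` has one row per motif vertex — bottom row ``(0,0)..(n-1,0)``
    followed by the left column ``(0,1)..(0,n-1)`` — holding the two free
    sector angles in degrees.  Lengths are in dimensionless design units:
    crease segments along the bottom row and the left column, plus the four
    boundary spokes (west and south of vertex ``(0,0)``, east of ``(n-1,0)``,
    north of ``(0,n-1)``).
    """

    free_angles: np.ndarray
    bottom_lengths: np.ndarray
    left_lengths: np.ndarray
    spoke_lengths: np.ndarray = field(default_factory=lambda: np.ones(4))

    def __post_init__(self):
        self.free_angles = np.asarray(self.free_angles, dtype=float)
        self.bottom_lengths = np.asarray(self.bottom_lengths, dtype=float)
        self.left_lengths = np.asarray(self.left_lengths, dtype=float)
        self.spoke_lengths = np.asarray(self.spoke_lengths, dtype=float)
        n = self.grid_size
        if self.free_angles.shape != (2 * n - 1, 2):
            raise ValueError("free_angles must have shape (2n - 1, 2)")
        if self.left_lengths.shape != (n - 1,) or self.spoke_lengths.shape != (4,):
            raise ValueError("inconsistent length arrays")

    @property
    def grid_size(self) -> int:
        return len(self.bottom_lengths) + 1

    @property
    def n_free_parameters(self) -> int:
        return self.free_angles.size + self.n_lengths

    @property
    def n_lengths(self) -> int:
        return self.bottom_lengths.size + self.left_lengths.size + 4

    def as_vector(self) -> np.ndarray:
        return np.concatenate(
            [
                self.free_angles.ravel(),
                self.bottom_lengths,
                self.left_lengths,
                self.spoke_lengths,
            ]
        )

    @classmethod
    def from_vector(cls, x: np.ndarray, grid_size: int) -> "MotifParameters":
        x = np.asarray(x, dtype=float)
        n = grid_size
        na = 2 * (2 * n - 1)
        angles = x[:na].reshape(2 * n - 1, 2)
        rest = x[na:]
        nb = n - 1
        return cls(
            free_angles=angles,
            bottom_lengths=rest[:nb],
            left_lengths=rest[nb : 2 * nb],
            spoke_lengths=rest[2 * nb : 2 * nb + 4],
        )

    def validate(self) -> None:
        lo, hi = ANGLE_MARGIN_DEG, 180.0 - ANGLE_MARGIN_DEG
        if np.any(self.free_angles <= lo) or np.any(self.free_angles >= hi):
            raise InfeasiblePatternError(
                "angle-out-of-range",
                f"sector angles must lie in ({lo}, {hi}) degrees",
            )
        for arr in (self.bottom_lengths, self.left_lengths, self.spoke_lengths):
            if np.any(arr <= 0):
                raise InfeasiblePatternError("negative-length", "crease length <= 0")

    def copy(self) -> "MotifParameters":
        return MotifParameters(
            self.free_angles.copy(),
            self.bottom_lengths.copy(),
            self.left_lengths.copy(),
            self.spoke_lengths.copy(),
        )


def complete_vertex_angles(free_pair, *, margin: float = ANGLE_MARGIN_DEG):
    """Complete a flat-foldable degree-4 vertex from its two free angles.

    Returns ``(a1, a2, 180 - a1, 180 - a2)`` in degrees (Kawasaki's alternating
    sums are exactly 180).  Raises :class:`DegenerateVertexError` when the two
    free angles coincide: then two opposite creases become collinear and the
    fold-angle multiplier is singular (e.g. the pair ``(90, 90)``).
    """
    a1, a2 = float(free_pair[0]), float(free_pair[1])
    for a in (a1, a2):
        if not 0.0 < a < 180.0:
            raise InfeasiblePatternError("angle-out-of-range", f"angle {a} deg")
    if abs(a1 - a2) < margin:
        raise DegenerateVertexError(
            f"free pair ({a1}, {a2}) gives collinear creases (singular vertex)"
        )
    return (a1, a2, 180.0 - a1, 180.0 - a2)


def fold_multiplier(theta_en: float, theta_nw: float) -> float:
    """Signed fold-angle multiplier of a flat-foldable degree-4 vertex.

    Arguments in degrees.  ``mu`` relates the tangent half fold angles of the
    creases through the vertex: ``tan(gamma_vertical/2) = mu *
    tan(gamma_horizontal/2)`` in the chain sign convention of the spherical
    four-bar closure at the vertex.
    """
    p = np.radians(theta_en)
    q = np.radians(theta_nw)
    denom = np.sin((q - p) / 2.0)
    if abs(denom) < 1e-12:
        raise DegenerateVertexError("singular fold multiplier (p == q)")
    return float(-np.sin((p + q) / 2.0) / denom)


@dataclass
class Motif:
    """A validated L-shaped motif: completed sector angles plus lengths."""

    params: MotifParameters
    sectors: np.ndarray  # (2n-1, 4) completed angles, motif-vertex order

    @property
    def grid_size(self) -> int:
        return self.params.grid_size

    @property
    def n_vertices(self) -> int:
        return 2 * self.grid_size - 1


def build_motif(params: MotifParameters) -> Motif:
    """Validate the 30 design variables and complete the motif vertices.

    Each motif vertex is completed via Kawasaki's condition; odd-parity
    vertices are mirrored so that a uniform motif reproduces the Miura-ori.
    """
    params.validate()
    n = params.grid_size
    sectors = np.empty((2 * n - 1, 4))
    for k in range(2 * n - 1):
        # motif order: bottom row (i, 0), i = 0..n-1, then left column (0, j)
        i, j = (k, 0) if k < n else (0, k - n + 1)
        a1, a2 = params.free_angles[k]
        if j % 2 == 1:
            a1, a2 = a2, a1
        comp = complete_vertex_angles((a1, a2))
        sectors[k] = comp  # (theta_WS, theta_SE, theta_EN, theta_NW)
    return Motif(params=params, sectors=sectors)


@dataclass
class CreasePattern:
    """A flat RFFQM crease pattern on the full ``(n+2) x (n+2)`` vertex grid.

    ``vid[r, c]`` maps grid row ``r`` (0 = bottom boundary) and column ``c``
    (0 = left boundary) to a vertex index; internal vertex ``(i, j)`` sits at
    ``vid[j + 1, i + 1]``.  ``sectors[j, i]`` stores the internal vertex
    angles ``(theta_WS, theta_SE, theta_EN, theta_NW)`` in degrees and
    ``dirs[j, i]`` the absolute crease direction angles ``(E, N, W, S)`` in
    radians.  Edge assignment letters are ``"M"``, ``"V"`` or ``"B"``.
    """

    grid_size: int
    vertices: np.ndarray  # (V, 2)
    vid: np.ndarray  # (n+2, n+2) int
    edges: np.ndarray  # (E, 2) int
    assignment: list  # len E of "M" / "V" / "B"
    faces: np.ndarray  # (F, 4) int
    sectors: np.ndarray  # (n, n, 4) degrees
    dirs: np.ndarray  # (n, n, 4) radians
    mu: np.ndarray  # (n, n) signed multipliers
    boundary_scale_factors: np.ndarray | None = None

    # -- indexing helpers ---------------------------------------------------
    @property
    def n_internal(self) -> int:
        return self.grid_size * self.grid_size

    def internal_vertex(self, i: int, j: int) -> int:
        return int(self.vid[j + 1, i + 1])

    def corner_vertices(self) -> np.ndarray:
        """The four boundary corner vertices (bl, br, tr, tl)."""
        m = self.grid_size + 1
        return np.array(
            [self.vid[0, 0], self.vid[0, m], self.vid[m, m], self.vid[m, 0]]
        )

    def edge_lengths(self) -> np.ndarray:
        p = self.vertices
        return np.linalg.norm(p[self.edges[:, 0]] - p[self.edges[:, 1]], axis=1)

    def internal_edge_mask(self) -> np.ndarray:
        return np.array([a != "B" for a in self.assignment])

    def edge_line(self) -> list:
        """Per-edge line key: ``("h", j)``, ``("v", i)`` or ``None`` (boundary).

        Every internal crease belongs to one horizontal row polyline or one
        vertical column polyline; the rigid folding assigns one fold-angle
        magnitude per line.
        """
        n = self.grid_size
        lut = {}
        for j in range(n):
            r = j + 1
            for c in range(n + 1):
                lut[frozenset((int(self.vid[r, c]), int(self.vid[r, c + 1])))] = ("h", j)
        for i in range(n):
            c = i + 1
            for r in range(n + 1):
                lut[frozenset((int(self.vid[r, c]), int(self.vid[r + 1, c])))] = ("v", i)
        return [lut.get(frozenset((int(a), int(b)))) for a, b in self.edges]

    def kawasaki_residual(self) -> float:
        """Max Kawasaki residual over internal vertices, degrees."""
        s = self.sectors
        r1 = np.abs(s[..., 0] + s[..., 2] - 180.0)
        r2 = np.abs(s[..., 1] + s[..., 3] - 180.0)
        return float(np.max(r1 + r2))

    def copy(self) -> "CreasePattern":
        return dataclasses.replace(
            self,
            vertices=self.vertices.copy(),
            assignment=list(self.assignment),
            boundary_scale_factors=None
            if self.boundary_scale_factors is None
            else self.boundary_scale_factors.copy(),
        )


def _ray_intersection(p0, d0, p1, d1):
    """Intersect rays ``p0 + t d0`` and ``p1 + u d1``; return (t, u, point)."""
    m = np.array([[d0[0], -d1[0]], [d0[1], -d1[1]]])
    det = m[0, 0] * m[1, 1] - m[0, 1] * m[1, 0]
    if abs(det) < 1e-14:
        return None
    rhs = np.asarray(p1) - np.asarray(p0)
    t = (rhs[0] * m[1, 1] - rhs[1] * m[0, 1]) / det
    u = (m[0, 0] * rhs[1] - m[1, 0] * rhs[0]) / det
    return t, u, np.asarray(p0) + t * np.asarray(d0)


def _unit(angle: float) -> np.ndarray:
    return np.array([np.cos(angle), np.sin(angle)])


def _solve_interior_angle(theta_ws_deg: float, mu_target: float) -> float:
    """Solve the unknown sector ``theta_NW`` of an interior vertex, degrees.

    Given the geometrically fixed panel angle ``theta_WS`` (hence
    ``theta_EN = 180 - theta_WS`` by Kawasaki) and the multiplier forced by the
    rank-1 compatibility condition, ``tan(q/2) = tan(p/2) (mu-1)/(mu+1)``.
    """
    p = np.radians(180.0 - theta_ws_deg)
    if abs(mu_target + 1.0) < 1e-12:
        raise InfeasiblePatternError("marching-divergence", "multiplier == -1")
    v = np.tan(p / 2.0) * (mu_target - 1.0) / (mu_target + 1.0)
    if v <= 0.0:
        raise InfeasiblePatternError(
            "marching-divergence", "no feasible interior vertex angle"
        )
    return float(np.degrees(2.0 * np.arctan(v)))


def march_pattern(motif: Motif) -> CreasePattern:
    """March the motif into the full crease pattern.

    Bottom-row and left-column vertices are placed from the motif lengths and
    angles; every interior vertex is the intersection of the north-going
    crease ray from below and the east-going crease ray from the left, with
    its free sector angle fixed by the rank-1 multiplier compatibility
    condition.  Boundary vertices are placed at provisional spoke lengths and
    later adjusted by :func:`rectangularize_boundary`.

    Raises :class:`InfeasiblePatternError` on marching divergence, negative
    lengths, out-of-range angles or intersecting creases.
    """
    n = motif.grid_size
    params = motif.params
    lo, hi = ANGLE_MARGIN_DEG, 180.0 - ANGLE_MARGIN_DEG

    pos = np.zeros((n, n, 2))
    dirs = np.zeros((n, n, 4))  # absolute angles of (E, N, W, S), radians
    sectors = np.zeros((n, n, 4))  # (theta_WS, theta_SE, theta_EN, theta_NW), deg
    mu = np.zeros((n, n))

    def set_dirs(i, j, anchor: str, angle: float):
        """Fill dirs[j, i] from one anchored crease direction (radians)."""
        t_ws, t_se, t_en, t_nw = np.radians(sectors[j, i])
        if anchor == "E":
            e = angle
        elif anchor == "W":
            e = angle + t_ws + t_se  # W -> S -> E going CCW
        elif anchor == "S":
            e = angle + t_se
        else:
            raise ValueError(anchor)
        dirs[j, i] = np.mod([e, e + t_en, e + t_en + t_nw, e - t_se], 2 * np.pi)

    # motif vertices: completed sectors
    for k in range(2 * n - 1):
        i, j = (k, 0) if k < n else (0, k - n + 1)
        sectors[j, i] = motif.sectors[k]
        mu[j, i] = fold_multiplier(sectors[j, i, 2], sectors[j, i, 3])

    # bottom row: chain eastwards
    set_dirs(0, 0, "E", 0.0)
    for i in range(1, n):
        d_e = dirs[0, i - 1, 0]
        pos[i, 0] = pos[i - 1, 0] + params.bottom_lengths[i - 1] * _unit(d_e)
        set_dirs(i, 0, "W", np.mod(d_e + np.pi, 2 * np.pi))
    # left column: chain northwards
    for j in range(1, n):
        d_n = dirs[j - 1, 0, 1]
        pos[0, j] = pos[0, j - 1] + params.left_lengths[j - 1] * _unit(d_n)
        set_dirs(0, j, "S", np.mod(d_n + np.pi, 2 * np.pi))

    # interior marching
    for j in range(1, n):
        for i in range(1, n):
            hit = _ray_intersection(
                pos[i, j - 1], _unit(dirs[j - 1, i, 1]),
                pos[i - 1, j], _unit(dirs[j, i - 1, 0]),
            )
            if hit is None:
                raise InfeasiblePatternError(
                    "marching-divergence", f"parallel crease rays at ({i}, {j})"
                )
            t, u, point = hit
            if t <= 1e-12 or u <= 1e-12:
                raise InfeasiblePatternError(
                    "negative-length", f"crease rays diverge at ({i}, {j})"
                )
            pos[i, j] = point
            d_s = np.mod(dirs[j - 1, i, 1] + np.pi, 2 * np.pi)
            d_w = np.mod(dirs[j, i - 1, 0] + np.pi, 2 * np.pi)
            theta_ws = np.degrees(np.mod(d_s - d_w, 2 * np.pi))
            if not lo < theta_ws < hi:
                raise InfeasiblePatternError(
                    "angle-out-of-range", f"panel angle {theta_ws:.3f} at ({i}, {j})"
                )
            mu_t = mu[j, 0] * mu[0, i] / mu[0, 0]
            q = _solve_interior_angle(theta_ws, mu_t)
            if not lo < q < hi:
                raise InfeasiblePatternError(
                    "angle-out-of-range", f"solved angle {q:.3f} at ({i}, {j})"
                )
            sectors[j, i] = (theta_ws, 180.0 - q, 180.0 - theta_ws, q)
            mu[j, i] = mu_t
            set_dirs(i, j, "W", d_w)

    return _assemble_pattern(n, params, pos, dirs, sectors, mu)


def _assemble_pattern(n, params, pos, dirs, sectors, mu) -> CreasePattern:
    """Place provisional boundary vertices and build the mesh arrays."""
    spoke_w, spoke_s, spoke_e, spoke_n = params.spoke_lengths

    m = n + 2  # full grid side
    verts = np.zeros((m * m, 2))
    vid = np.arange(m * m).reshape(m, m)
    for j in range(n):
        for i in range(n):
            verts[vid[j + 1, i + 1]] = pos[i, j]
    # side boundary vertices at provisional (per-side anchor) spoke lengths
    for i in range(n):
        verts[vid[0, i + 1]] = pos[i, 0] + spoke_s * _unit(dirs[0, i, 3])
        verts[vid[m - 1, i + 1]] = pos[i, n - 1] + spoke_n * _unit(dirs[n - 1, i, 1])
    for j in range(n):
        verts[vid[j + 1, 0]] = pos[0, j] + spoke_w * _unit(dirs[j, 0, 2])
        verts[vid[j + 1, m - 1]] = pos[n - 1, j] + spoke_e * _unit(dirs[j, n - 1, 0])
    # corners: provisional rectangle-free placement (fixed by rectangularize)
    verts[vid[0, 0]] = verts[vid[1, 0]] + (verts[vid[0, 1]] - verts[vid[1, 1]])
    verts[vid[0, m - 1]] = verts[vid[1, m - 1]] + (
        verts[vid[0, m - 2]] - verts[vid[1, m - 2]]
    )
    verts[vid[m - 1, 0]] = verts[vid[m - 2, 0]] + (
        verts[vid[m - 1, 1]] - verts[vid[m - 2, 1]]
    )
    verts[vid[m - 1, m - 1]] = verts[vid[m - 2, m - 1]] + (
        verts[vid[m - 1, m - 2]] - verts[vid[m - 2, m - 2]]
    )

    edges = []
    assignment = []
    for r in range(m):  # horizontal-ish grid edges
        for c in range(m - 1):
            edges.append((vid[r, c], vid[r, c + 1]))
            assignment.append("B" if r in (0, m - 1) else None)
    for c in range(m):  # vertical-ish grid edges
        for r in range(m - 1):
            edges.append((vid[r, c], vid[r + 1, c]))
            assignment.append("B" if c in (0, m - 1) else None)
    edges = np.array(edges, dtype=int)

    faces = []
    for r in range(m - 1):
        for c in range(m - 1):
            faces.append((vid[r, c], vid[r, c + 1], vid[r + 1, c + 1], vid[r + 1, c]))
    faces = np.array(faces, dtype=int)

    pat = CreasePattern(
        grid_size=n,
        vertices=verts,
        vid=vid,
        edges=edges,
        assignment=assignment,
        faces=faces,
        sectors=sectors,
        dirs=dirs,
        mu=mu,
    )
    assign_mountain_valley(pat)
    return pat


def assign_mountain_valley(pattern: CreasePattern) -> CreasePattern:
    """Label internal creases with the standard Miura-type assignment.

    Each vertical crease polyline carries a single label, alternating between
    columns; horizontal creases alternate at every vertex along their row, in
    a checkerboard with the row index.  Every internal vertex then satisfies
    Maekawa's count ``|M - V| = 2``, and (with valley read as positive fold
    angle) the resulting signed fold-angle field closes the spherical linkage
    at every internal vertex on the Miura-continuous folding branch.  The
    assignment is combinatorial, in place, and idempotent.
    """
    lines = pattern.edge_line()
    m = pattern.grid_size + 2
    for e, line in enumerate(lines):
        if line is None:
            pattern.assignment[e] = "B"
            continue
        kind, _ = line
        a, b = (int(v) for v in pattern.edges[e])
        r = min(a // m, b // m)
        c = min(a % m, b % m)
        if kind == "h":
            pattern.assignment[e] = "V" if (r + c) % 2 == 0 else "M"
        else:
            pattern.assignment[e] = "V" if c % 2 == 1 else "M"
    return pattern


def rectangularize_boundary(pattern: CreasePattern) -> CreasePattern:
    """Scale boundary spokes so the boundary is an axis-aligned rectangle.

    Each side of the rectangle carries one free offset, anchored so that the
    motif's spoke on that side keeps its design length (scale factor 1); the
    remaining spokes on the side are stretched along their own crease
    directions until their endpoints lie exactly on the side line.  Interior
    geometry is untouched; the operation is idempotent.
    """
    n = pattern.grid_size
    m = n + 2
    vid = pattern.vid
    verts = pattern.vertices
    pat = pattern.copy()
    out = pat.vertices

    # side lines from the anchor spokes (canonical frame: x along first crease)
    y_bot = verts[vid[0, 1]][1]
    y_top = verts[vid[m - 1, 1]][1]
    x_left = verts[vid[1, 0]][0]
    x_right = verts[vid[1, m - 1]][0]
    if not (y_bot < y_top and x_left < x_right):
        raise InfeasiblePatternError("marching-divergence", "degenerate boundary box")

    def stretch(anchor_vid, base_vid, axis, target):
        base = verts[base_vid]
        d = verts[anchor_vid] - base
        if abs(d[axis]) < 1e-14:
            raise InfeasiblePatternError(
                "marching-divergence", "boundary spoke parallel to side"
            )
        t = (target - base[axis]) / d[axis]
        if t <= 0:
            raise InfeasiblePatternError("negative-length", "boundary spoke scale <= 0")
        out[anchor_vid] = base + t * d

    for i in range(n):
        stretch(vid[0, i + 1], vid[1, i + 1], 1, y_bot)
        stretch(vid[m - 1, i + 1], vid[m - 2, i + 1], 1, y_top)
    for j in range(n):
        stretch(vid[j + 1, 0], vid[j + 1, 1], 0, x_left)
        stretch(vid[j + 1, m - 1], vid[j + 1, m - 2], 0, x_right)
    out[vid[0, 0]] = (x_left, y_bot)
    out[vid[0, m - 1]] = (x_right, y_bot)
    out[vid[m - 1, m - 1]] = (x_right, y_top)
    out[vid[m - 1, 0]] = (x_left, y_top)

    # scale factor definition: achieved side offset over the anchor offset
    pat.boundary_scale_factors = np.array(
        [
            (y_bot - verts[vid[1, 1]][1]) / (verts[vid[0, 1]][1] - verts[vid[1, 1]][1]),
            (y_top - verts[vid[m - 2, 1]][1])
            / (verts[vid[m - 1, 1]][1] - verts[vid[m - 2, 1]][1]),
            (x_left - verts[vid[1, 1]][0]) / (verts[vid[1, 0]][0] - verts[vid[1, 1]][0]),
            (x_right - verts[vid[1, m - 2]][0])
            / (verts[vid[1, m - 1]][0] - verts[vid[1, m - 2]][0]),
        ]
    )
    validate_pattern(pat)
    return pat


def _cross2(a, b) -> float:
    return float(a[0] * b[1] - a[1] * b[0])


def _segments_intersect(p1, p2, p3, p4) -> bool:
    """Exact-ish 2D open-segment intersection (shared endpoints excluded)."""
    d1 = _cross2(p4 - p3, p1 - p3)
    d2 = _cross2(p4 - p3, p2 - p3)
    d3 = _cross2(p2 - p1, p3 - p1)
    d4 = _cross2(p2 - p1, p4 - p1)
    eps = 1e-12
    return (d1 * d2 < -eps) and (d3 * d4 < -eps)


def validate_pattern(pattern: CreasePattern) -> None:
    """Check CreasePattern invariants; raise :class:`InfeasiblePatternError`.

    Verifies the Kawasaki residual, positive crease lengths, simple positively
    oriented panels and the absence of crossing creases (exact segment test
    over all non-adjacent pairs; quadratic but cheap at this mesh size).
    """
    if pattern.kawasaki_residual() >= 1e-9:
        raise InfeasiblePatternError("kawasaki-violation", "Kawasaki residual")
    if np.any(pattern.edge_lengths() <= 1e-12):
        raise InfeasiblePatternError("negative-length", "zero-length crease")
    p = pattern.vertices
    for quad in pattern.faces:
        q = p[quad]
        area2 = _cross2(q[1] - q[0], q[2] - q[0]) + _cross2(q[2] - q[0], q[3] - q[0])
        if area2 <= 1e-12:
            raise InfeasiblePatternError("crease-intersection", "flipped panel")
    E = pattern.edges
    for a in range(len(E)):
        for b in range(a + 1, len(E)):
            if set(E[a]) & set(E[b]):
                continue
            if _segments_intersect(p[E[a][0]], p[E[a][1]], p[E[b][0]], p[E[b][1]]):
                raise InfeasiblePatternError(
                    "crease-intersection", f"edges {a} and {b} cross"
                )


def build_pattern(params: MotifParameters) -> CreasePattern:
    """Full chain: motif -> march -> rectangularize -> MV assignment."""
    return rectangularize_boundary(march_pattern(build_motif(params)))


def try_build_pattern(params: MotifParameters):
    """Like :func:`build_pattern` but returning ``(pattern, diagnostics)``."""
    try:
        pat = build_pattern(params)
    except DegenerateVertexError as exc:
        return None, PatternDiagnostics(False, "kawasaki-violation", str(exc))
    except InfeasiblePatternError as exc:
        return None, PatternDiagnostics(False, exc.reason, str(exc))
    return pat, PatternDiagnostics(True)


def miura_reference(
    beta: float = 60.0, a: float = 1.0, b: float = 1.0, grid_size: int = 5
) -> MotifParameters:
    """Motif parameters of the uniform Miura-ori seed.

    ``beta`` is the acute Miura sector angle in degrees; ``a`` and ``b`` the
    horizontal and zigzag crease lengths.  All free pairs equal
    ``(beta, 180 - beta)``; marching reproduces the periodic Miura pattern.
    """
    if not 0.0 < beta < 90.0:
        raise ValueError("beta must be in (0, 90) degrees")
    if a <= 0 or b <= 0:
        raise ValueError("lengths must be positive")
    n = grid_size
    angles = np.tile([beta, 180.0 - beta], (2 * n - 1, 1))
    return MotifParameters(
        free_angles=angles,
        bottom_lengths=np.full(n - 1, a),
        left_lengths=np.full(n - 1, b),
        spoke_lengths=np.array([a, b, a, b]),
    )


def perturb_motif(
    params: MotifParameters, sigma: float, seed: int | None = None
) -> MotifParameters:
    """Add Gaussian noise (std ``sigma`` degrees) to the lower-left free pair.

    Emulates manufacturing imperfections: noise on the two free sector angles
    of the lower-left motif vertex propagates through the marching recurrence
    and perturbs the full pattern.  Deterministic under ``seed``.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    out = params.copy()
    out.free_angles[0] = out.free_angles[0] + rng.normal(0.0, sigma, size=2)
    out.validate()
    return out
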
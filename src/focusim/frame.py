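"""Global alignment, scaling and design constraints of the folded transducer.

Folded states are aligned so that the least-squares plane through the four
boundary corner vertices becomes parallel to the xy-plane, the corner
rectangle's long edge runs along x, and the corner centroid sits at the
origin.  The aligned transducer is then scaled by a single factor ``s`` (mm
per design unit) so that the xy-projected area at the shallowest design
folding state (rho = 5 degrees) meets the area budget exactly.

Four design constraints keep the design practically actuable:

1. dihedral angles between adjacent facets stay below 120 degrees;
2. crease lengths (design units) stay within (0.4, 2.0), i.e. physical
   lengths within ``(0.4 s, 2.0 s)`` mm;
3. the folded structure's z-extent stays below 7 mm;
4. corner vertices deviate from the fitted plane by less than 2 mm along z.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull

from .kinematics import FoldedState, facet_dihedrals
from .pattern import CreasePattern

DEFAULT_AREA_CAP_MM2 = 400.0
MAX_DIHEDRAL_DEG = 120.0
CREASE_BOUNDS = (0.4, 2.0)
MAX_HEIGHT_MM = 7.0
MAX_CORNER_Z_MM = 2.0


class AlignmentError(ValueError):
    """Corner vertices are collinear; the global frame is undefined."""


@dataclass
class RigidTransform:
    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation


@dataclass
class AlignedState:
    """A folded state expressed in the global transducer frame."""

    state: FoldedState
    transform: RigidTransform
    corner_ids: np.ndarray  # (4,) vertex indices (bl, br, tr, tl in the flat pattern)

    @property
    def coords(self) -> np.ndarray:
        return self.state.coords

    def corners(self) -> np.ndarray:
        return self.state.coords[self.corner_ids]


def _plane_normal(points: np.ndarray) -> np.ndarray:
    c = points - points.mean(axis=0)
    _, sing, vt = np.linalg.svd(c, full_matrices=False)
    if sing[1] < 1e-12 * max(sing[0], 1.0):
        raise AlignmentError("corner vertices are collinear")
    n = vt[2]
    return n if n[2] >= 0 else -n


def align_state(state: FoldedState, pattern: CreasePattern) -> AlignedState:
    """Rigidly move a folded state into the canonical global frame.

    The least-squares plane of the four corner vertices maps to a plane
    parallel to ``z = 0`` (normal kept pointing up), the long edge of the
    corner rectangle maps to the x-axis (ties broken towards the edge
    adjacent to the anchor panel, i.e. the bottom edge) and the corner
    centroid to the origin.  No scaling is applied.
    """
    corner_ids = pattern.corner_vertices()
    corners = state.coords[corner_ids]
    n = _plane_normal(corners)

    # rotation taking n -> z
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(n, z)
    s = np.linalg.norm(v)
    c = float(np.dot(n, z))
    if s < 1e-15:
        R1 = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R1 = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)

    p = corners @ R1.T
    bottom = p[1] - p[0]  # bl -> br
    left = p[3] - p[0]  # bl -> tl
    e = bottom if np.linalg.norm(bottom) >= np.linalg.norm(left) - 1e-12 else left
    ang = np.arctan2(e[1], e[0])
    ca, sa = np.cos(-ang), np.sin(-ang)
    R2 = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1.0]])
    R = R2 @ R1
    t = -(corners @ R.T).mean(axis=0)

    tf = RigidTransform(rotation=R, translation=t)
    new = FoldedState(
        coords=tf.apply(state.coords),
        rho=state.rho,
        face_normals=state.face_normals @ R.T,
        closure_residual=state.closure_residual,
    )
    return AlignedState(state=new, transform=tf, corner_ids=corner_ids)


def projected_area(state: AlignedState, method: str = "hull") -> float:
    """xy-projected area of the folded transducer, squared design units.

    ``"hull"`` (default) takes the 2D convex hull of all projected vertices —
    conservative and rotation-stable; ``"facets"`` sums the projected facet
    areas instead.
    """
    xy = state.coords[:, :2]
    if method != "hull":
        raise ValueError("use projected_facet_area(state, pattern) for facet sums")
    return float(ConvexHull(xy).volume)


def projected_facet_area(state: AlignedState, pattern: CreasePattern) -> float:
    """Sum of xy-projected panel areas (alternative area measure)."""
    total = 0.0
    for quad in pattern.faces:
        q = state.coords[quad][:, :2]
        total += 0.5 * abs(
            np.cross(q[1] - q[0], q[2] - q[0]) + np.cross(q[2] - q[0], q[3] - q[0])
        )
    return float(total)


def compute_scale(
    states: list, area_cap: float = DEFAULT_AREA_CAP_MM2, method: str = "hull"
) -> float:
    """Scale factor ``s`` (mm per design unit) meeting the area budget.

    The first state must be the shallowest design folding state (rho = 5
    degrees); its projected area scaled by ``s**2`` equals ``area_cap``
    exactly (small designs are scaled up, large ones down).
    """
    area = projected_area(states[0], method=method)
    if area <= 0:
        raise ValueError("zero-area projection")
    return float(np.sqrt(area_cap / area))


def scale_states(states: list, s: float) -> list:
    """Apply the uniform scale to aligned states (coords become mm)."""
    out = []
    for st in states:
        new = FoldedState(
            coords=st.state.coords * s,
            rho=st.state.rho,
            face_normals=st.state.face_normals.copy(),
            closure_residual=st.state.closure_residual,
        )
        out.append(AlignedState(state=new, transform=st.transform, corner_ids=st.corner_ids))
    return out


def corner_trajectories(states: list) -> np.ndarray:
    """Corner positions across folding states, shape ``(4, n_states, 3)``."""
    if len(states) < 2:
        if not states:
            raise ValueError("need at least one state")
    return np.stack([st.corners() for st in states], axis=1)


@dataclass
class ConstraintReport:
    """Worst-case constraint values over a folding-state sweep."""

    max_dihedral: float  # degrees
    crease_length_bounds: tuple  # (min, max) of l / s
    max_height: float  # mm, z extent
    max_corner_z: float  # mm
    passed: tuple  # four flags

    @property
    def all_passed(self) -> bool:
        return all(self.passed)


def evaluate_constraints(
    states: list, pattern: CreasePattern, s: float
) -> ConstraintReport:
    """Evaluate the four design constraints on scaled, aligned states.

    ``states`` must already be scaled to mm; the report aggregates worst
    cases over all supplied folding states.
    """
    mask = pattern.internal_edge_mask()
    max_dih = 0.0
    max_height = 0.0
    max_cz = 0.0
    for st in states:
        dih = facet_dihedrals(st.state, pattern)
        max_dih = max(max_dih, float(dih[mask].max()) if mask.any() else 0.0)
        z = st.coords[:, 2]
        max_height = max(max_height, float(z.max() - z.min()))
        max_cz = max(max_cz, float(np.abs(st.corners()[:, 2]).max()))
    lengths = pattern.edge_lengths()[mask]  # design units == l / s
    lo, hi = float(lengths.min()), float(lengths.max())
    passed = (
        max_dih <= MAX_DIHEDRAL_DEG,
        CREASE_BOUNDS[0] < lo and hi < CREASE_BOUNDS[1],
        max_height <= MAX_HEIGHT_MM,
        max_cz <= MAX_CORNER_Z_MM,
    )
    return ConstraintReport(
        max_dihedral=max_dih,
        crease_length_bounds=(lo, hi),
        max_height=max_height,
        max_corner_z=max_cz,
        passed=passed,
    )


def aligned_scaled_sweep(
    pattern: CreasePattern,
    rhos,
    area_cap: float = DEFAULT_AREA_CAP_MM2,
):
    """Fold, align and scale a pattern over a driving-angle schedule.

    Returns ``(states, s)`` with coordinates in mm; the first rho sets the
    scale via the area budget.
    """
    from .kinematics import fold_sweep

    folded = fold_sweep(pattern, rhos)
    aligned = [align_state(st, pattern) for st in folded]
    s = compute_scale(aligned, area_cap)
    return scale_states(aligned, s), s
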
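"""FOLD-format import/export for crease patterns and folded states.

FOLD is the JSON-based origami interchange format (``vertices_coords``,
``edges_vertices``, ``edges_assignment``, ``faces_vertices``); assignments
use the letters ``"M"``, ``"V"`` and ``"B"``.  Pattern metadata that FOLD
has no standard field for (grid size, sector angles, multipliers) is stored
under ``focusim:``-prefixed custom keys so that round trips are exact.
Folded states carry 3D coordinates plus per-edge fold angles.
"""

from __future__ import annotations

import json

import numpy as np

from .kinematics import FoldAngleField, FoldedState
from .pattern import CreasePattern


def pattern_to_fold(pattern: CreasePattern) -> dict:
    d = {
        "file_spec": 1.1,
        "file_creator": "focusim",
        "frame_class": "creasePattern",
        "vertices_coords": pattern.vertices.tolist(),
        "edges_vertices": pattern.edges.tolist(),
        "edges_assignment": list(pattern.assignment),
        "faces_vertices": pattern.faces.tolist(),
        "focusim:grid_size": pattern.grid_size,
        "focusim:vid": pattern.vid.tolist(),
        "focusim:sectors": pattern.sectors.tolist(),
        "focusim:dirs": pattern.dirs.tolist(),
        "focusim:mu": pattern.mu.tolist(),
    }
    if pattern.boundary_scale_factors is not None:
        d["focusim:boundary_scale_factors"] = pattern.boundary_scale_factors.tolist()
    return d


def fold_to_pattern(d: dict) -> CreasePattern:
    bsf = d.get("focusim:boundary_scale_factors")
    return CreasePattern(
        grid_size=int(d["focusim:grid_size"]),
        vertices=np.asarray(d["vertices_coords"], dtype=float),
        vid=np.asarray(d["focusim:vid"], dtype=int),
        edges=np.asarray(d["edges_vertices"], dtype=int),
        assignment=list(d["edges_assignment"]),
        faces=np.asarray(d["faces_vertices"], dtype=int),
        sectors=np.asarray(d["focusim:sectors"], dtype=float),
        dirs=np.asarray(d["focusim:dirs"], dtype=float),
        mu=np.asarray(d["focusim:mu"], dtype=float),
        boundary_scale_factors=None if bsf is None else np.asarray(bsf, dtype=float),
    )


def save_pattern(pattern: CreasePattern, path) -> None:
    with open(path, "w") as fh:
        json.dump(pattern_to_fold(pattern), fh)


def load_pattern(path) -> CreasePattern:
    with open(path) as fh:
        return fold_to_pattern(json.load(fh))


def folded_state_to_fold(
    state: FoldedState, pattern: CreasePattern, angles: FoldAngleField | None = None
) -> dict:
    d = {
        "file_spec": 1.1,
        "file_creator": "focusim",
        "frame_class": "foldedForm",
        "vertices_coords": state.coords.tolist(),
        "edges_vertices": pattern.edges.tolist(),
        "edges_assignment": list(pattern.assignment),
        "faces_vertices": pattern.faces.tolist(),
        "focusim:rho": state.rho,
    }
    if angles is not None:
        d["edges_foldAngle"] = angles.gamma.tolist()
    return d


def save_folded_state(
    state: FoldedState, pattern: CreasePattern, path, angles=None
) -> None:
    with open(path, "w") as fh:
        json.dump(folded_state_to_fold(state, pattern, angles), fh)


def load_folded_state(path):
    """Return ``(coords, rho, fold_angles_or_None)`` from a foldedForm file."""
    with open(path) as fh:
        d = json.load(fh)
    coords = np.asarray(d["vertices_coords"], dtype=float)
    gam = d.get("edges_foldAngle")
    return coords, float(d.get("focusim:rho", np.nan)), None if gam is None else np.asarray(gam)
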
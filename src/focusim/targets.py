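"""Synthetic imaging targets: point scatterers and vessel-like structures.

Targets emulate sparse optoacoustic absorption maps: isolated point
scatterers, connected vessel-like trees (correlated random walks with
branching) and sparse 3D scatterer volumes.  Each target is defined by a
*scene* — point coordinates or vessel polylines in millimetres — from which
rasters on any field-of-view grid are derived, so the same scene can be
rendered on the fine (data-generation) and coarse (reconstruction) grids
without ever resampling pixels.  All generators are pure functions of their
parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import line as _draw_line
from scipy.ndimage import binary_dilation, label

from .acoustics import FieldOfView

#: maximum allowed fraction of nonzero pixels in a generated target
SPARSITY_CAP = 0.10


@dataclass
class TargetImage:
    """A nonnegative [0, 1] image with its generating scene description."""

    values: np.ndarray  # grid-shaped, in [0, 1]
    kind: str  # "points", "vessel" or "volume"
    seed: int | None
    scene: dict = field(default_factory=dict)
    fov: FieldOfView | None = None

    def __post_init__(self):
        v = self.values
        if v.min() < 0 or v.max() > 1:
            raise ValueError("target values must lie in [0, 1]")

    @property
    def sparsity(self) -> float:
        return float(np.count_nonzero(self.values) / self.values.size)

    def render(self, fov: FieldOfView) -> "TargetImage":
        """Re-rasterize the scene on a different grid (same scene, new pitch)."""
        return _render_scene(self.scene, self.kind, fov, self.seed)


def _mm_to_index(fov: FieldOfView, xy_mm: np.ndarray) -> np.ndarray:
    """Map scene mm coordinates to (row, col[, slab]) pixel indices."""
    p = fov.pitch_um * 1e-3
    ax0 = -(fov.n - 1) / 2.0 * p
    idx = np.rint((xy_mm - ax0) / p).astype(int)
    return np.clip(idx, 0, fov.n - 1)


def _render_scene(scene: dict, kind: str, fov: FieldOfView, seed) -> TargetImage:
    img = np.zeros(fov.shape)
    if kind in ("points", "volume"):
        for pt in scene["points"]:
            coords = np.asarray(pt["mm"])
            amp = pt["amp"]
            ij = _mm_to_index(fov, coords)
            # scene order is (x, y[, z]); rasters index (row=y, col=x[, slab=z])
            if fov.dims == 2:
                img[ij[1], ij[0]] = max(img[ij[1], ij[0]], amp)
            else:
                img[ij[2], ij[1], ij[0]] = max(img[ij[2], ij[1], ij[0]], amp)
    elif kind == "vessel":
        mask = np.zeros(fov.shape, dtype=bool)
        for poly in scene["polylines"]:
            pts = _mm_to_index(fov, np.asarray(poly))  # (K, 2) as (x, y) idx
            for (c0, r0), (c1, r1) in zip(pts[:-1], pts[1:]):
                rr, cc = _draw_line(r0, c0, r1, c1)
                mask[rr, cc] = True
        width = scene.get("width_px", 1)
        if width > 1:
            mask = binary_dilation(mask, iterations=width - 1)
        img[mask] = 1.0
    else:
        raise ValueError(kind)
    return TargetImage(values=img, kind=kind, seed=seed, scene=scene, fov=fov)


def point_targets(
    n_points: int,
    fov: FieldOfView,
    amplitude_range=(0.5, 1.0),
    seed: int | None = None,
) -> TargetImage:
    """Exactly ``n_points`` distinct scatterer pixels with random amplitudes."""
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    if n_points > fov.n_points:
        raise ValueError("more points than grid pixels")
    rng = np.random.default_rng(seed)
    flat = rng.choice(fov.n_points, size=n_points, replace=False)
    p = fov.pitch_um * 1e-3
    ax = (np.arange(fov.n) - (fov.n - 1) / 2.0) * p
    pts = []
    for f in flat:
        if fov.dims == 2:
            r, c = divmod(int(f), fov.n)
            mm = (ax[c], ax[r])
        else:
            s, rc = divmod(int(f), fov.n * fov.n)
            r, c = divmod(rc, fov.n)
            mm = (ax[c], ax[r], ax[s])
        amp = float(rng.uniform(*amplitude_range))
        pts.append({"mm": mm, "amp": amp})
    scene = {"points": pts}
    return _render_scene(scene, "points" if fov.dims == 2 else "volume", fov, seed)


def vessel_targets(
    fov: FieldOfView,
    n_branches: int = 2,
    step_mm: float | None = None,
    curliness: float = 0.35,
    width_px: int = 1,
    seed: int | None = None,
) -> TargetImage:
    """A connected vessel-like tree from a correlated random walk.

    The trunk starts at a random edge point heading inward; headings evolve
    by wrapped-Gaussian increments of scale ``curliness`` (radians).  Each
    branch forks from a random trunk vertex with a heading offset.  The
    foreground is rasterized at unit amplitude with the given width and is a
    single connected component by construction.
    """
    if curliness < 0 or width_px < 1 or n_branches < 0:
        raise ValueError("parameters must be positive")
    rng = np.random.default_rng(seed)
    half = fov.extent_mm / 2.0
    if step_mm is None:
        step_mm = 2.5 * fov.pitch_um * 1e-3

    def walk(start, heading, n_steps):
        pts = [np.asarray(start, dtype=float)]
        h = heading
        for _ in range(n_steps):
            h += rng.normal(0.0, curliness)
            nxt = pts[-1] + step_mm * np.array([np.cos(h), np.sin(h)])
            if np.any(np.abs(nxt) > half * 0.98):
                break
            pts.append(nxt)
        return np.array(pts)

    side = rng.integers(4)
    u = rng.uniform(-0.8, 0.8) * half
    start = [(-half * 0.95, u), (half * 0.95, u), (u, -half * 0.95), (u, half * 0.95)][side]
    inward = [0.0, np.pi, np.pi / 2, -np.pi / 2][side]
    trunk = walk(start, inward + rng.normal(0, 0.3), int(1.2 * fov.n))
    polylines = [trunk]
    for _ in range(n_branches):
        if len(trunk) < 3:
            break
        k = int(rng.integers(1, len(trunk) - 1))
        head = np.arctan2(*(trunk[k] - trunk[k - 1])[::-1]) + rng.choice([-1, 1]) * rng.uniform(0.5, 1.2)
        polylines.append(walk(trunk[k], head, int(0.5 * fov.n)))
    scene = {"polylines": [p.tolist() for p in polylines], "width_px": width_px}
    return _render_scene(scene, "vessel", fov, seed)


def is_connected(img: np.ndarray) -> bool:
    """True when the nonzero foreground forms one 8-connected component."""
    mask = img > 0
    if not mask.any():
        return False
    _, n = label(mask, structure=np.ones((3, 3), dtype=int))
    return n == 1


def make_training_set(K: int = 28, fov: FieldOfView | None = None, seed: int | None = 0):
    """``K`` point-scatterer targets (1-10 points each), no vessels.

    Per-image seeds are spawned from the master seed so the set is
    deterministic and images are mutually independent.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    fov = fov or FieldOfView(extent_mm=8.0, pitch_um=100.0)
    ss = np.random.SeedSequence(seed)
    out = []
    for k, child in enumerate(ss.spawn(K)):
        sub = int(child.generate_state(1)[0] % (2**31))
        out.append(point_targets(1 + k % 10, fov, seed=sub))
    return out


def make_test_set(fov: FieldOfView | None = None, seed: int | None = 1):
    """Eight test targets: four point-scatterer and four vessel images."""
    fov = fov or FieldOfView(extent_mm=8.0, pitch_um=100.0)
    ss = np.random.SeedSequence((seed, 0xF0C05))
    seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(8)]
    out = [point_targets(2 + 2 * k, fov, seed=seeds[k]) for k in range(4)]
    out += [vessel_targets(fov, n_branches=1 + k % 3, seed=seeds[4 + k]) for k in range(4)]
    return out


def volume_target(
    fov3d: FieldOfView, n_scatterers: int = 3, seed: int | None = None
) -> TargetImage:
    """Sparse 3D scatterer arrangement on an ``N^3`` voxel grid."""
    if fov3d.dims != 3:
        raise ValueError("fov must be 3D")
    return point_targets(n_scatterers, fov3d, amplitude_range=(0.6, 1.0), seed=seed)
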
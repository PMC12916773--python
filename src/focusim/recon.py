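"""Total-variation-regularized least-squares image reconstruction.

Solves ``x_hat = argmin ||A x - y||^2 + lambda1 ||x||_1 + lambda2 TV(x)``
over nonnegative images with mini-batch Adam, matching the single-channel
multi-state measurement model: ``A`` is the column-normalized imaging matrix
and ``y`` the unit-norm measurement.  Nonnegativity is enforced by clipping
after every step; the iteration stops when the full-data objective has not
improved for ``patience`` consecutive iterations.  Also provides the image
quality metrics (relative L2 error and SSIM) used to score reconstructions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import correlate

from .acoustics import ImagingMatrix, Measurement


@dataclass
class ReconstructionConfig:
    """Hyperparameters of the stochastic TV least-squares solver."""

    lambda1: float = 1e-4  # L1 sparsity weight
    lambda2: float = 1e-4  # total-variation weight
    lr: float = 2e-5  # Adam step size
    batch: int = 1000  # mini-batch rows
    patience: int = 500  # non-improving iterations before stopping
    max_iter: int = 50000
    seed: int | None = 0
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    isotropic_tv: bool = False
    improve_rtol: float = 1e-10  # relative decrease counting as improvement

    def __post_init__(self):
        for name in ("lambda1", "lambda2", "lr", "batch", "patience", "max_iter"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class Reconstruction:
    """Reconstructed image on the (coarse) reconstruction grid."""

    x_hat: np.ndarray  # grid-shaped, values in [0, 1]
    loss_history: np.ndarray  # full objective per iteration
    n_iter: int = 0


def total_variation(x: np.ndarray, shape=None, isotropic: bool = False) -> float:
    """Anisotropic (default) or isotropic total variation of a gridded image.

    Anisotropic: sum over axes of absolute forward differences (the last
    difference along each axis is omitted).  Works for 2D and 3D grids.
    """
    img = np.asarray(x, dtype=float)
    if shape is not None:
        img = img.reshape(shape)
    diffs = [np.diff(img, axis=ax) for ax in range(img.ndim)]
    if not isotropic:
        return float(sum(np.abs(d).sum() for d in diffs))
    # isotropic: L2 norm of the forward-difference vector on the common grid
    common = tuple(np.min([d.shape for d in diffs], axis=0))
    core = [d[tuple(slice(0, s) for s in common)] for d in diffs]
    return float(np.sqrt(sum(c**2 for c in core)).sum())


def tv_subgradient(x: np.ndarray) -> np.ndarray:
    """Subgradient of the anisotropic TV (zero at ties)."""
    g = np.zeros_like(x)
    for ax in range(x.ndim):
        s = np.sign(np.diff(x, axis=ax))
        pre = [slice(None)] * x.ndim
        post = [slice(None)] * x.ndim
        pre[ax] = slice(0, -1)
        post[ax] = slice(1, None)
        g[tuple(pre)] -= s
        g[tuple(post)] += s
    return g


def reconstruct(
    A: ImagingMatrix | np.ndarray,
    y: Measurement | np.ndarray,
    cfg: ReconstructionConfig | None = None,
    grid_shape: tuple | None = None,
) -> Reconstruction:
    """Reconstruct a nonnegative [0, 1] image from stacked measurements.

    ``A`` may be an :class:`ImagingMatrix` (its ``A_tilde`` and field-of-view
    shape are used) or a plain matrix with unit-norm columns plus an explicit
    ``grid_shape``.  The measurement is normalized to unit L2 norm, making
    the result invariant to positive rescaling of ``y``.  Deterministic
    under ``cfg.seed``.
    """
    cfg = cfg or ReconstructionConfig()
    if isinstance(A, ImagingMatrix):
        mat = A.A_tilde
        if grid_shape is None and A.fov is not None:
            grid_shape = A.fov.shape
    else:
        mat = np.asarray(A, dtype=float)
    yv = np.asarray(y.y_bar if isinstance(y, Measurement) else y, dtype=float).ravel()
    if mat.shape[0] != yv.shape[0]:
        raise ValueError("row count of A and length of y differ")
    if grid_shape is None:
        grid_shape = (mat.shape[1],)
    ynorm = np.linalg.norm(yv)
    if ynorm == 0:
        warnings.warn("all-zero measurement: returning the zero image")
        return Reconstruction(np.zeros(grid_shape), np.zeros(0), 0)
    yt = yv / ynorm

    rows = mat.shape[0]
    batch = min(cfg.batch, rows)
    rng = np.random.default_rng(cfg.seed)
    x = np.zeros(mat.shape[1])
    m = np.zeros_like(x)
    v = np.zeros_like(x)
    best = np.inf
    best_x = x.copy()
    stall = 0
    losses = []
    perm = rng.permutation(rows)
    pos = 0
    for it in range(1, cfg.max_iter + 1):
        if pos + batch > rows:
            perm = rng.permutation(rows)
            pos = 0
        sel = perm[pos : pos + batch]
        pos += batch
        Ab = mat[sel]
        resid = Ab @ x - yt[sel]
        grad = 2.0 * (Ab.T @ resid)
        grad += cfg.lambda1 * np.sign(x)
        grad += cfg.lambda2 * tv_subgradient(x.reshape(grid_shape)).ravel()
        m = cfg.adam_beta1 * m + (1 - cfg.adam_beta1) * grad
        v = cfg.adam_beta2 * v + (1 - cfg.adam_beta2) * grad**2
        mh = m / (1 - cfg.adam_beta1**it)
        vh = v / (1 - cfg.adam_beta2**it)
        x -= cfg.lr * mh / (np.sqrt(vh) + cfg.adam_eps)
        np.maximum(x, 0.0, out=x)  # rectification promotes sparsity

        r = mat @ x - yt
        loss = float(r @ r) + cfg.lambda1 * float(np.abs(x).sum())
        loss += cfg.lambda2 * total_variation(x.reshape(grid_shape))
        losses.append(loss)
        if loss < best * (1.0 - cfg.improve_rtol):
            best = loss
            best_x = x.copy()
            stall = 0
        else:
            stall += 1
            if stall >= cfg.patience:
                break

    out = best_x.reshape(grid_shape)
    peak = out.max()
    if peak > 0:
        out = out / peak
    return Reconstruction(x_hat=out, loss_history=np.asarray(losses), n_iter=len(losses))


def l2_error(x_true: np.ndarray, x_hat: np.ndarray) -> float:
    """Euclidean norm of the pixel-wise difference of two [0, 1] images."""
    a = np.asarray(x_true, dtype=float)
    b = np.asarray(x_hat, dtype=float)
    if a.shape != b.shape:
        raise ValueError("image shapes differ")
    return float(np.linalg.norm((a - b).ravel()))


def _gaussian_kernel(sigma: float, size: int, ndim: int) -> np.ndarray:
    r = np.arange(size) - (size - 1) / 2.0
    k1 = np.exp(-(r**2) / (2 * sigma**2))
    k1 /= k1.sum()
    k = k1
    for _ in range(ndim - 1):
        k = np.multiply.outer(k, k1)
    return k


def ssim_index(
    x_true: np.ndarray,
    x_hat: np.ndarray,
    data_range: float = 1.0,
    sigma: float = 1.5,
    win_size: int = 11,
    K1: float = 0.01,
    K2: float = 0.03,
) -> float:
    """Mean structural similarity index of two images (2D or 3D).

    Standard Gaussian-weighted SSIM (11-point window, sigma 1.5); the local
    map is averaged over the interior region unaffected by edge padding.
    Falls back to a smaller window (with a warning) for tiny images.
    """
    a = np.asarray(x_true, dtype=float)
    b = np.asarray(x_hat, dtype=float)
    if a.shape != b.shape:
        raise ValueError("image shapes differ")
    if min(a.shape) < win_size:
        win_size = min(a.shape) if min(a.shape) % 2 == 1 else min(a.shape) - 1
        warnings.warn(f"image smaller than SSIM window; using win_size={win_size}")
    k = _gaussian_kernel(sigma, win_size, a.ndim)

    def filt(img):
        return correlate(img, k, mode="nearest")

    ua, ub = filt(a), filt(b)
    vaa = filt(a * a) - ua * ua
    vbb = filt(b * b) - ub * ub
    vab = filt(a * b) - ua * ub
    C1 = (K1 * data_range) ** 2
    C2 = (K2 * data_range) ** 2
    s = ((2 * ua * ub + C1) * (2 * vab + C2)) / (
        (ua**2 + ub**2 + C1) * (vaa + vbb + C2)
    )
    pad = (win_size - 1) // 2
    core = s[tuple(slice(pad, dim - pad) for dim in s.shape)]
    return float(core.mean())
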
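"""Acoustic forward model: spatial impulse responses and imaging matrices.

The folded transducer surface is discretized into small planar elements; the
received pressure at a field point in response to a Dirac excitation is the
superposition of monopole contributions ``area / (2 pi r)`` delayed by the
time of flight ``r / c`` (rigid-baffle far-field model, reciprocity between
transmit and receive).  Fractional delays are spread linearly over the two
bracketing samples of the ``fs`` grid.

The total impulse response (TIR) of folding state ``i`` is the per-pixel
convolution ``A_i = h * h_e * h_er`` of the impulse field with the excitation
pulse and the electromechanical impulse response, both modeled as
Dolph-Chebyshev-windowed cosines at the central frequency ``fc`` whose
combined -6 dB bandwidth is the transducer bandwidth ``fb``.  Stacking the
states row-wise gives the imaging matrix ``A_bar`` (shape ``S T x N^2``) and
its column-normalized form ``A_tilde``.

Measurements follow the linear model ``y = A_fine x_fine + noise``; data
generation and reconstruction use different grids (80 vs 100 um defaults) so
that no reconstruction is ever tested against its own discrete model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve
from scipy.signal.windows import chebwin

MM = 1e-3
UM = 1e-6


@dataclass
class SimulationConfig:
    """Acoustic simulation parameters (SI units).

    ``n_cycles`` controls the pulse duration and is tuned so that the
    combined excitation/electromechanical response has a -6 dB bandwidth of
    ``fb`` around ``fc`` (1 MHz at 2 MHz by default).  ``element_cap`` is the
    largest allowed acoustic element edge; the default is an eighth of a
    wavelength.
    """

    c: float = 1500.0  # speed of sound, m/s
    fs: float = 50e6  # sampling frequency, Hz
    fc: float = 2e6  # pulse central frequency, Hz
    fb: float = 1e6  # transducer -6 dB bandwidth, Hz
    n_cycles: float = 3.7  # pulse length in periods of fc (bandwidth-tuned)
    cheb_attenuation_db: float = 100.0
    element_cap: float | None = None  # m; default c / (8 fc)
    obliquity: bool = False  # optional cos(theta) element directivity
    delay_mode: str = "linear"  # or "nearest"

    def __post_init__(self):
        if self.element_cap is None:
            self.element_cap = self.c / (8.0 * self.fc)
        if self.fs <= 10.0 * self.fc:
            raise ValueError("fs must exceed 10 * fc")
        if self.element_cap > self.c / (8.0 * self.fc) * (1 + 1e-12):
            raise ValueError("element_cap must not exceed c / (8 fc)")


@dataclass
class FieldOfView:
    """Pixel/voxel grid of the imaging region, transducer-frame coordinates.

    2D: an ``N x N`` lateral (xy) grid at depth ``depth_mm`` below/above the
    transducer plane.  3D: an ``N^3`` voxel cube centred at that depth.
    """

    extent_mm: float
    pitch_um: float
    depth_mm: float = 17.0
    dims: int = 2

    def __post_init__(self):
        ratio = self.extent_mm * 1e3 / self.pitch_um
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("extent must be an integer multiple of pitch")

    @property
    def n(self) -> int:
        return int(round(self.extent_mm * 1e3 / self.pitch_um))

    @property
    def n_points(self) -> int:
        return self.n**self.dims

    def axis_mm(self) -> np.ndarray:
        p = self.pitch_um * 1e-3
        return (np.arange(self.n) - (self.n - 1) / 2.0) * p

    def points(self) -> np.ndarray:
        """Grid point coordinates in meters, shape ``(n_points, 3)``.

        2D points are ordered row-major (y outer, x inner); 3D adds z as the
        outermost axis, centred on ``depth_mm``.
        """
        ax = self.axis_mm()
        if self.dims == 2:
            Y, X = np.meshgrid(ax, ax, indexing="ij")
            Z = np.full_like(X, self.depth_mm)
        elif self.dims == 3:
            Zc, Y, X = np.meshgrid(ax, ax, ax, indexing="ij")
            Z = Zc + self.depth_mm
        else:
            raise ValueError("dims must be 2 or 3")
        pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1) * MM
        return pts

    @property
    def shape(self) -> tuple:
        return (self.n,) * self.dims


@dataclass
class ElementCloud:
    """Planar acoustic surface elements of one folded state."""

    centers: np.ndarray  # (E, 3) m
    areas: np.ndarray  # (E,) m^2
    normals: np.ndarray  # (E, 3) unit

    @property
    def n_elements(self) -> int:
        return len(self.areas)

    @property
    def total_area(self) -> float:
        return float(self.areas.sum())


def discretize_surface(state, pattern, cap: float) -> ElementCloud:
    """Subdivide each panel of an aligned, scaled state into elements.

    ``state`` is an :class:`~focusim.frame.AlignedState` with coordinates in
    mm; the cloud is returned in meters.  Sub-quads are sized so that no
    element edge exceeds ``cap``; centers, areas and normals are exact for
    planar panels.
    """
    if cap <= 0:
        raise ValueError("cap must be positive")
    coords = state.coords * MM
    centers, areas, normals = [], [], []
    for f, quad in enumerate(pattern.faces):
        q = coords[quad]  # corners A, B, C, D (CCW)
        du = max(np.linalg.norm(q[1] - q[0]), np.linalg.norm(q[2] - q[3]))
        dv = max(np.linalg.norm(q[3] - q[0]), np.linalg.norm(q[2] - q[1]))
        nu = max(1, int(np.ceil(du / cap)))
        nv = max(1, int(np.ceil(dv / cap)))
        u = np.linspace(0, 1, nu + 1)
        v = np.linspace(0, 1, nv + 1)
        U, V = np.meshgrid(u, v, indexing="ij")
        # bilinear parametrization of the planar quad
        P = (
            np.multiply.outer((1 - U) * (1 - V), q[0])
            + np.multiply.outer(U * (1 - V), q[1])
            + np.multiply.outer(U * V, q[2])
            + np.multiply.outer((1 - U) * V, q[3])
        )
        a = P[:-1, :-1]
        b = P[1:, :-1]
        c = P[1:, 1:]
        d = P[:-1, 1:]
        cent = (a + b + c + d) / 4.0
        cr = 0.5 * (np.cross(c - a, d - b))
        ar = np.linalg.norm(cr, axis=-1)
        nrm = cr / ar[..., None]
        centers.append(cent.reshape(-1, 3))
        areas.append(ar.ravel())
        normals.append(nrm.reshape(-1, 3))
    return ElementCloud(
        centers=np.concatenate(centers),
        areas=np.concatenate(areas),
        normals=np.concatenate(normals),
    )


def _max_distance(cloud: ElementCloud, pts: np.ndarray) -> float:
    """Largest element-to-point distance, chunked over elements."""
    P = len(pts)
    chunk = max(1, int(4e6 // max(P, 1)))
    r_max = 0.0
    for lo in range(0, cloud.n_elements, chunk):
        d = pts[None, :, :] - cloud.centers[lo : lo + chunk, None, :]
        r_max = max(r_max, float(np.sqrt(np.einsum("epk,epk->ep", d, d)).max()))
    return r_max


def time_window(r_max: float, cfg: SimulationConfig, pulse_len: int) -> int:
    """Number of time samples covering the farthest time of flight plus pulse."""
    return int(np.ceil(cfg.fs * r_max / cfg.c)) + 2 * pulse_len + 2


def impulse_response(
    cloud: ElementCloud, fov: FieldOfView, cfg: SimulationConfig, T: int
) -> np.ndarray:
    """Dirac-excitation received field ``h``, shape ``(T, n_points)``.

    ``h[:, p]`` is the sum over elements of ``area / (2 pi r)`` delayed by
    ``r / c``, with fractional delays linearly interpolated between the two
    bracketing samples (or snapped, with ``delay_mode="nearest"``).
    """
    pts = fov.points()
    P = len(pts)
    h = np.zeros(T * P)
    cols = np.arange(P)
    # chunk over elements to bound the (E, P) intermediates
    chunk = max(1, int(4e6 // max(P, 1)))
    for lo in range(0, cloud.n_elements, chunk):
        cen = cloud.centers[lo : lo + chunk]
        diff = pts[None, :, :] - cen[:, None, :]  # (e, P, 3)
        r = np.sqrt(np.einsum("epk,epk->ep", diff, diff))
        if np.any(r <= 0):
            raise ValueError("field point coincides with an element")
        amp = cloud.areas[lo : lo + chunk, None] / (2.0 * np.pi * r)
        if cfg.obliquity:
            cosv = (
                np.abs(np.einsum("epk,ek->ep", diff, cloud.normals[lo : lo + chunk]))
                / r
            )
            amp = amp * cosv
        idx = r * (cfg.fs / cfg.c)
        if idx.max() >= T - 1:
            raise ValueError("time window too short for the farthest field point")
        cgrid = np.broadcast_to(cols, idx.shape)
        if cfg.delay_mode == "nearest":
            i0 = np.rint(idx).astype(np.int64)
            h += np.bincount(
                (i0 * P + cgrid).ravel(), weights=amp.ravel(), minlength=T * P
            )
        else:
            i0 = np.floor(idx).astype(np.int64)
            w = idx - i0
            flat = (i0 * P + cgrid).ravel()
            h += np.bincount(flat, weights=(amp * (1.0 - w)).ravel(), minlength=T * P)
            h += np.bincount(flat + P, weights=(amp * w).ravel(), minlength=T * P)
    return h.reshape(T, P)


def windowed_cosine_pulse(
    fc: float,
    n_cycles: float,
    attenuation_db: float,
    fs: float,
) -> np.ndarray:
    """Dolph-Chebyshev-windowed cosine pulse, unit energy.

    The pulse lasts ``n_cycles`` periods of ``fc``; the window's sidelobe
    attenuation is ``attenuation_db``.  Spectral peak sits at ``fc``.
    """
    if fc >= fs / 2:
        raise ValueError("fc must be below Nyquist")
    n = max(3, int(round(n_cycles * fs / fc)))
    t = (np.arange(n) - (n - 1) / 2.0) / fs
    p = np.cos(2.0 * np.pi * fc * t) * chebwin(n, at=attenuation_db)
    return p / np.linalg.norm(p)


def combined_pulse(cfg: SimulationConfig) -> np.ndarray:
    """Excitation convolved with the electromechanical response, unit energy."""
    he = windowed_cosine_pulse(cfg.fc, cfg.n_cycles, cfg.cheb_attenuation_db, cfg.fs)
    her = windowed_cosine_pulse(cfg.fc, cfg.n_cycles, cfg.cheb_attenuation_db, cfg.fs)
    q = np.convolve(he, her)
    return q / np.linalg.norm(q)


def bandwidth_6db(pulse: np.ndarray, fs: float, nfft: int = 1 << 16) -> float:
    """-6 dB spectral width of a pulse, Hz (amplitude half-maximum)."""
    spec = np.abs(np.fft.rfft(pulse, nfft))
    f = np.fft.rfftfreq(nfft, 1.0 / fs)
    half = spec.max() / 2.0
    above = spec >= half
    i = np.flatnonzero(above)
    # linear interpolation at the crossings
    lo, hi = i[0], i[-1]

    def cross(j, k):
        return f[j] + (half - spec[j]) * (f[k] - f[j]) / (spec[k] - spec[j])

    f_lo = f[0] if lo == 0 else cross(lo - 1, lo)
    f_hi = f[-1] if hi == len(f) - 1 else cross(hi + 1, hi)
    return float(f_hi - f_lo)


def assemble_tir(h: np.ndarray, h_e: np.ndarray, h_er: np.ndarray) -> np.ndarray:
    """Total impulse response ``A_i = h * h_e * h_er`` truncated to T rows."""
    T = h.shape[0]
    pulse = np.convolve(h_e, h_er)
    out = fftconvolve(h, pulse[:, None], axes=0)
    return out[:T]


@dataclass
class ImagingMatrix:
    """Row-stacked TIRs of all folding states and the normalized copy."""

    A_bar: np.ndarray  # (S T, P)
    A_tilde: np.ndarray  # (S T, P), unit columns (zero columns untouched)
    state_index: np.ndarray  # (S T,) folding-state index per row
    rhos: np.ndarray  # (S,) driving angles, degrees
    zero_columns: np.ndarray  # indices of all-zero columns
    fov: FieldOfView | None = None

    @property
    def n_states(self) -> int:
        return len(self.rhos)

    @property
    def T(self) -> int:
        return self.A_bar.shape[0] // self.n_states


def stack_and_normalize(A_list, rhos, fov: FieldOfView | None = None) -> ImagingMatrix:
    """Stack per-state TIRs in rho order and column-normalize.

    All-zero columns (field points invisible to the transducer) are flagged
    and left unnormalized.
    """
    A_bar = np.vstack(A_list)
    norms = np.linalg.norm(A_bar, axis=0)
    zero = np.flatnonzero(norms == 0)
    safe = np.where(norms == 0, 1.0, norms)
    A_tilde = A_bar / safe
    T = A_list[0].shape[0]
    state_index = np.repeat(np.arange(len(A_list)), T)
    return ImagingMatrix(
        A_bar=A_bar,
        A_tilde=A_tilde,
        state_index=state_index,
        rhos=np.asarray(rhos, dtype=float),
        zero_columns=zero,
        fov=fov,
    )


@dataclass
class Measurement:
    """Stacked single-channel time series over folding states."""

    y_bar: np.ndarray  # (S T,)
    snr_db: float
    seed: int | None
    noise: np.ndarray | None = None


def simulate_measurement(
    A_fine: ImagingMatrix,
    x_fine: np.ndarray,
    snr_db: float = np.inf,
    seed: int | None = None,
) -> Measurement:
    """Noisy measurement ``y = A_fine x + n`` at the requested SNR.

    Gaussian white noise is scaled so ``10 log10(||A x||^2 / ||n||^2)``
    equals ``snr_db``; infinite SNR adds none.  Deterministic under ``seed``.
    """
    x = np.asarray(x_fine, dtype=float).ravel()
    y = A_fine.A_bar @ x
    if np.isinf(snr_db):
        return Measurement(y_bar=y, snr_db=snr_db, seed=seed, noise=None)
    power = float(np.sum(y**2))
    if power == 0:
        raise ValueError("SNR undefined for an all-zero signal")
    rng = np.random.default_rng(seed)
    n = rng.standard_normal(len(y))
    n *= np.sqrt(power / 10 ** (snr_db / 10.0)) / np.linalg.norm(n)
    return Measurement(y_bar=y + n, snr_db=snr_db, seed=seed, noise=n)


def compute_imaging_matrix(
    pattern,
    fov: FieldOfView,
    cfg: SimulationConfig,
    rhos=None,
    area_cap: float = 400.0,
    T: int | None = None,
) -> ImagingMatrix:
    """Full forward chain: fold, align, scale, discretize, simulate, stack.

    By default the time window is sized from the farthest element-to-point
    distance over all states so that stacking is well defined; pass an
    explicit ``T`` to share a window between matrices on different grids.
    """
    from .frame import aligned_scaled_sweep
    from .kinematics import default_driving_angles

    if rhos is None:
        rhos = default_driving_angles(8)
    states, s = aligned_scaled_sweep(pattern, rhos, area_cap=area_cap)
    clouds = [discretize_surface(st, pattern, cfg.element_cap) for st in states]
    pulse = combined_pulse(cfg)
    if T is None:
        pts = fov.points()
        r_max = max(_max_distance(c, pts) for c in clouds)
        T = time_window(r_max, cfg, len(pulse))
    A_list = []
    for cloud in clouds:
        h = impulse_response(cloud, fov, cfg, T)
        A_list.append(fftconvolve(h, pulse[:, None], axes=0)[:T])
    return stack_and_normalize(A_list, rhos, fov=fov)


def imaging_matrix_pair(
    pattern,
    fov_recon: FieldOfView,
    fov_sim: FieldOfView,
    cfg: SimulationConfig,
    rhos=None,
    area_cap: float = 400.0,
):
    """Reconstruction- and simulation-grid matrices with one shared window.

    The two matrices are built independently (distinct grids, distinct
    objects — no inverse crime) but share the time axis so that measurements
    simulated with one can be inverted with the other.  Returns
    ``(A_recon, A_sim)``.
    """
    from .frame import aligned_scaled_sweep
    from .kinematics import default_driving_angles

    if rhos is None:
        rhos = default_driving_angles(8)
    states, _ = aligned_scaled_sweep(pattern, rhos, area_cap=area_cap)
    clouds = [discretize_surface(st, pattern, cfg.element_cap) for st in states]
    pulse = combined_pulse(cfg)
    r_max = max(
        _max_distance(c, fov.points())
        for fov in (fov_recon, fov_sim)
        for c in clouds
    )
    T = time_window(r_max, cfg, len(pulse))
    A_r = compute_imaging_matrix(pattern, fov_recon, cfg, rhos, area_cap, T=T)
    A_s = compute_imaging_matrix(pattern, fov_sim, cfg, rhos, area_cap, T=T)
    return A_r, A_s


def measured_snr(m: Measurement) -> float:
    """Recompute the realized SNR of a stored measurement, dB."""
    if m.noise is None:
        return np.inf
    sig = m.y_bar - m.noise
    return float(10.0 * np.log10(np.sum(sig**2) / np.sum(m.noise**2)))
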
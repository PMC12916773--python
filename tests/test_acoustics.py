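"""Acoustic forward model: elements, impulse responses, pulses, stacking."""

import numpy as np
import pytest

from focusim import acoustics as fa
from focusim import frame as ff


@pytest.fixture(scope="module")
def flat_square_state(miura_pattern):
    states, s = ff.aligned_scaled_sweep(miura_pattern, [5.0])
    return states[0]


def unit_cloud(r_mm=0.0):
    return fa.ElementCloud(
        centers=np.array([[0.0, 0.0, r_mm * 1e-3]]),
        areas=np.array([1e-8]),
        normals=np.array([[0.0, 0.0, 1.0]]),
    )


def test_config_invariants():
    cfg = fa.SimulationConfig()
    assert cfg.element_cap == pytest.approx(1500.0 / (8 * 2e6))
    with pytest.raises(ValueError):
        fa.SimulationConfig(fs=15e6)  # fs must exceed 10 fc
    with pytest.raises(ValueError):
        fa.SimulationConfig(element_cap=1e-3)  # above lambda / 8


def test_fov_grid():
    fov = fa.FieldOfView(extent_mm=8.0, pitch_um=80.0)
    assert fov.n == 100 and fov.n_points == 10000
    fov3 = fa.FieldOfView(extent_mm=4.0, pitch_um=500.0, dims=3)
    assert fov3.n_points == 8**3
    with pytest.raises(ValueError):
        fa.FieldOfView(extent_mm=8.0, pitch_um=77.0)


def test_discretize_flat_square():
    """A 1 mm x 1 mm flat panel at cap 0.25 mm becomes 16 exact elements."""
    from focusim.frame import AlignedState, RigidTransform
    from focusim.kinematics import FoldedState
    from focusim.pattern import CreasePattern

    verts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
    pat = CreasePattern(
        grid_size=0,
        vertices=verts,
        vid=np.zeros((1, 1), dtype=int),
        edges=np.array([[0, 1], [1, 2], [2, 3], [3, 0]]),
        assignment=["B"] * 4,
        faces=np.array([[0, 1, 2, 3]]),
        sectors=np.zeros((0, 0, 4)),
        dirs=np.zeros((0, 0, 4)),
        mu=np.zeros((0, 0)),
    )
    st = AlignedState(
        state=FoldedState(
            coords=np.hstack([verts, np.zeros((4, 1))]),
            rho=0.0,
            face_normals=np.array([[0.0, 0.0, 1.0]]),
        ),
        transform=RigidTransform(np.eye(3), np.zeros(3)),
        corner_ids=np.arange(4),
    )
    cloud = fa.discretize_surface(st, pat, cap=0.25e-3)
    assert cloud.n_elements == 16
    assert cloud.total_area == pytest.approx(1e-6, rel=1e-12)
    # halving the cap quadruples the count
    cloud2 = fa.discretize_surface(st, pat, cap=0.125e-3)
    assert cloud2.n_elements == 64


def test_area_conservation(flat_square_state, miura_pattern):
    cloud = fa.discretize_surface(flat_square_state, miura_pattern, cap=2e-4)
    exact = 0.0
    for quad in miura_pattern.faces:
        q = flat_square_state.coords[quad] * 1e-3
        exact += 0.5 * np.linalg.norm(
            np.cross(q[2] - q[0], q[3] - q[1])
        )
    assert cloud.total_area == pytest.approx(exact, rel=1e-6)


def test_time_of_flight_peak():
    """Element at origin, point at 15 mm, c = 1500 m/s: peak at 10 us."""
    cfg = fa.SimulationConfig()
    fov = fa.FieldOfView(extent_mm=0.08, pitch_um=80.0, depth_mm=15.0)
    h = fa.impulse_response(unit_cloud(), fov, cfg, T=600)
    assert np.argmax(h[:, 0]) / cfg.fs == pytest.approx(10e-6, abs=1.5 / cfg.fs)


def test_spherical_spreading_and_superposition():
    cfg = fa.SimulationConfig()
    fov1 = fa.FieldOfView(extent_mm=0.08, pitch_um=80.0, depth_mm=15.0)
    fov2 = fa.FieldOfView(extent_mm=0.08, pitch_um=80.0, depth_mm=30.0)
    h1 = fa.impulse_response(unit_cloud(), fov1, cfg, T=1200)
    h2 = fa.impulse_response(unit_cloud(), fov2, cfg, T=1200)
    assert h1[:, 0].sum() == pytest.approx(2 * h2[:, 0].sum(), rel=1e-9)
    # two equidistant elements double the amplitude
    two = fa.ElementCloud(
        centers=np.array([[0.5e-3, 0, 0], [-0.5e-3, 0, 0]]),
        areas=np.array([1e-8, 1e-8]),
        normals=np.tile([0.0, 0.0, 1.0], (2, 1)),
    )
    fovc = fa.FieldOfView(extent_mm=0.08, pitch_um=80.0, depth_mm=15.0)
    hc = fa.impulse_response(two, fovc, cfg, T=1200)
    one = fa.ElementCloud(
        centers=np.array([[0.5e-3, 0, 0]]),
        areas=np.array([1e-8]),
        normals=np.array([[0.0, 0.0, 1.0]]),
    )
    ho = fa.impulse_response(one, fovc, cfg, T=1200)
    assert hc[:, 0].sum() == pytest.approx(2 * ho[:, 0].sum(), rel=1e-9)


def test_first_arrival_sample(flat_square_state, miura_pattern):
    cfg = fa.SimulationConfig(fc=0.5e6, fs=10e6)
    cloud = fa.discretize_surface(flat_square_state, miura_pattern, cfg.element_cap)
    fov = fa.FieldOfView(extent_mm=4.0, pitch_um=2000.0, depth_mm=17.0)
    T = 400
    h = fa.impulse_response(cloud, fov, cfg, T)
    pts = fov.points()
    for p in range(fov.n_points):
        r_min = np.linalg.norm(pts[p] - cloud.centers, axis=1).min()
        first = np.flatnonzero(h[:, p])[0]
        assert abs(first - np.floor(cfg.fs * r_min / cfg.c)) <= 1


def test_pulse_properties():
    p = fa.windowed_cosine_pulse(2e6, 3.7, 100.0, 50e6)
    assert np.sum(p**2) == pytest.approx(1.0, abs=1e-12)
    spec = np.abs(np.fft.rfft(p, 1 << 16))
    f = np.fft.rfftfreq(1 << 16, 1 / 50e6)
    assert abs(f[np.argmax(spec)] - 2e6) < 50e6 / (1 << 16) + 1e3
    with pytest.raises(ValueError):
        fa.windowed_cosine_pulse(30e6, 3.7, 100.0, 50e6)


def test_combined_bandwidth():
    """Excitation * electromechanical response has a 1.0 +- 0.1 MHz width."""
    cfg = fa.SimulationConfig()
    bw = fa.bandwidth_6db(fa.combined_pulse(cfg), cfg.fs)
    assert bw == pytest.approx(1e6, abs=0.1e6)


def test_assemble_tir_algebra():
    rng = np.random.default_rng(0)
    h = rng.standard_normal((64, 5))
    delta = np.zeros(9)
    delta[0] = 1.0
    assert np.allclose(fa.assemble_tir(h, delta, delta), h, atol=1e-12)
    he = rng.standard_normal(11)
    her = rng.standard_normal(7)
    assert np.allclose(
        fa.assemble_tir(h, he, her), fa.assemble_tir(h, her, he), atol=1e-10
    )
    assert np.allclose(
        fa.assemble_tir(2 * h, he, her), 2 * fa.assemble_tir(h, he, her), atol=1e-10
    )


def test_stack_and_normalize():
    rng = np.random.default_rng(1)
    A_list = [rng.standard_normal((40, 9)) for _ in range(3)]
    A_list[0][:, 4] = 0.0
    A_list[1][:, 4] = 0.0
    A_list[2][:, 4] = 0.0
    M = fa.stack_and_normalize(A_list, rhos=[5, 10, 15])
    assert M.A_bar.shape == (120, 9)
    norms = np.linalg.norm(M.A_tilde, axis=0)
    assert np.allclose(np.delete(norms, 4), 1.0, atol=1e-12)
    assert list(M.zero_columns) == [4]
    assert np.array_equal(M.state_index, np.repeat([0, 1, 2], 40))
    single = fa.stack_and_normalize([A_list[0]], rhos=[5])
    assert np.array_equal(single.A_bar, A_list[0])


def test_measurement_model():
    rng = np.random.default_rng(2)
    A = fa.stack_and_normalize([rng.standard_normal((50, 16))], rhos=[5])
    x = np.zeros(16)
    x[3] = 1.0
    clean = fa.simulate_measurement(A, x, snr_db=np.inf)
    assert np.allclose(clean.y_bar, A.A_bar[:, 3], atol=1e-12)
    noisy = fa.simulate_measurement(A, x, snr_db=10.0, seed=7)
    assert fa.measured_snr(noisy) == pytest.approx(10.0, abs=0.05)
    again = fa.simulate_measurement(A, x, snr_db=10.0, seed=7)
    assert np.array_equal(noisy.y_bar, again.y_bar)
    with pytest.raises(ValueError):
        fa.simulate_measurement(A, np.zeros(16), snr_db=10.0)
    assert np.all(fa.simulate_measurement(A, np.zeros(16), snr_db=np.inf).y_bar == 0)


def test_3d_fov_matrix(toy3_pattern):
    cfg = fa.SimulationConfig(fc=0.25e6, fs=5e6)
    fov = fa.FieldOfView(extent_mm=4.0, pitch_um=1000.0, depth_mm=17.0, dims=3)
    M = fa.compute_imaging_matrix(toy3_pattern, fov, cfg, rhos=[10.0, 25.0])
    assert M.A_bar.shape[1] == 4**3
    assert np.allclose(np.linalg.norm(M.A_tilde, axis=0), 1.0, atol=1e-9)
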
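"""Design scoring (coherence, validation), LHS, MADS, sensitivity field."""

import numpy as np
import pytest

from focusim import design as fd
from focusim import acoustics as fa
from focusim.pattern import miura_reference


def test_mcp_oracle_brute_force():
    rng = np.random.default_rng(0)
    M = rng.standard_normal((50, 10))
    Mn = M / np.linalg.norm(M, axis=0)
    brute = (
        100.0
        * 2.0
        / (10 * 9)
        * sum(
            float(Mn[:, i] @ Mn[:, j]) ** 2 for i in range(10) for j in range(i + 1, 10)
        )
    )
    assert fd.mcp_objective(M) == pytest.approx(brute, abs=1e-10)
    # blockwise path agrees with the one-shot Gram computation
    assert fd.mcp_objective(M, block=3) == pytest.approx(brute, abs=1e-10)


def test_mcp_extremes_and_bounds():
    assert fd.mcp_objective(np.eye(12)) == 0.0
    assert fd.mcp_objective(np.ones((6, 2))) == pytest.approx(100.0)
    rng = np.random.default_rng(1)
    for _ in range(5):
        M = rng.standard_normal((30, 8))
        v = fd.mcp_objective(M)
        assert 0.0 <= v <= 100.0


def test_mcp_invariances():
    rng = np.random.default_rng(2)
    M = rng.standard_normal((40, 9))
    M /= np.linalg.norm(M, axis=0)
    base = fd.mcp_objective(M)
    perm = M[:, rng.permutation(9)]
    flip = M * np.where(rng.random(9) < 0.5, -1.0, 1.0)
    assert fd.mcp_objective(perm) == pytest.approx(base, abs=1e-12)
    assert fd.mcp_objective(flip) == pytest.approx(base, abs=1e-12)


def test_mcp_zero_column_rejected():
    M = np.eye(5)
    M[:, 2] = 0.0
    with pytest.raises(ValueError):
        fd.mcp_objective(M)


def test_lhs_stratification():
    pts = fd.lhs_sample([[0.0, 1.0]], 4, seed=1).ravel()
    assert sorted(np.floor(pts * 4).astype(int).tolist()) == [0, 1, 2, 3]
    a = fd.lhs_sample([[0, 1], [-2, 2]], 16, seed=3)
    b = fd.lhs_sample([[0, 1], [-2, 2]], 16, seed=3)
    assert np.array_equal(a, b)
    for d, (lo, hi) in enumerate([(0, 1), (-2, 2)]):
        strata = np.floor((a[:, d] - lo) / (hi - lo) * 16).astype(int)
        assert sorted(strata.tolist()) == list(range(16))
    with pytest.raises(ValueError):
        fd.lhs_sample([[0, 1]], 0)


def test_mads_on_convex_quadratic():
    opt = np.array([0.3, 0.7, 0.2, 0.5, 0.9])

    def f(x):
        return float(np.sum((x - opt) ** 2))

    res = fd.mads_optimize(
        f,
        [[0, 1]] * 5,
        fd.OptimizerConfig(max_evals=2000, lhs_evals=30, seed=2),
        seed_point=np.full(5, 0.5),
    )
    assert res.evals_used <= 2000
    assert np.linalg.norm(res.best_params - opt) < 1e-3 or res.best_value < 1e-3
    # history contains only strictly improving evaluations, seed first
    vals = [v for _, v in res.history]
    assert all(a > b for a, b in zip(vals, vals[1:]))
    assert res.history[0][0] == 1
    assert res.best_value == vals[-1]


def test_mads_extreme_barrier():
    """Points in the barrier region (+inf) never become incumbents."""

    def f(x):
        if x[0] > 0.5:
            return np.inf
        return float((x[0] - 0.4) ** 2 + x[1] ** 2)

    res = fd.mads_optimize(
        f, [[0, 1]] * 2, fd.OptimizerConfig(max_evals=300, lhs_evals=20, seed=0),
        seed_point=np.array([0.2, 0.8]),
    )
    assert res.best_params[0] <= 0.5
    assert np.isfinite(res.best_value)


def test_sensitivity_correlation():
    rng = np.random.default_rng(3)
    dup = np.tile(rng.standard_normal((50, 1)), (1, 4))
    c = fd.sensitivity_correlation(dup)
    assert c.mean == pytest.approx(1.0)
    assert c.hist[-1] == 6  # all 6 off-diagonal pairs at |corr| = 1
    # variance equals a direct two-pass computation
    M = rng.standard_normal((200, 12))
    c2 = fd.sensitivity_correlation(M)
    Z = (M - M.mean(axis=0)) / np.linalg.norm(M - M.mean(axis=0), axis=0)
    vals = []
    for i in range(12):
        for j in range(i + 1, 12):
            vals.append(abs(float(Z[:, i] @ Z[:, j])))
    vals = np.array(vals)
    assert c2.variance == pytest.approx(vals.var(), abs=1e-12)
    assert c2.mean == pytest.approx(vals.mean(), abs=1e-12)
    # independent long columns decorrelate
    big = fd.sensitivity_correlation(rng.standard_normal((1000, 30)))
    assert big.mean < 0.1
    # constant column excluded with a warning
    M2 = rng.standard_normal((60, 5))
    M2[:, 1] = 3.0
    with pytest.warns(UserWarning):
        fd.sensitivity_correlation(M2)


def test_evaluate_design_penalty_and_value():
    dcfg = fd.DesignConfig(
        fov=fa.FieldOfView(extent_mm=20.0, pitch_um=2000.0, depth_mm=17.0),
        rhos=np.array([10.0, 25.0]),
        grid_size=2,
    )
    ev = fd.DesignEvaluator(dcfg, fa.SimulationConfig(fc=0.25e6, fs=5e6))
    # infeasible motif (marching failure) -> finite 1e6 penalty
    bad = miura_reference(60.0, grid_size=2)
    bad.free_angles[0] = (170.0, 11.0)
    assert ev(bad) == fd.INFEASIBLE_PENALTY
    # Miura seed -> finite coherence value in (0, 100]
    v = ev(miura_reference(60.0, grid_size=2))
    assert 0.0 < v <= 100.0
    # cache hit: second call does not re-evaluate
    n = ev.n_evals
    ev(miura_reference(60.0, grid_size=2))
    assert ev.n_evals == n


def test_evaluate_design_constraint_barrier():
    """A design breaking the crease-length constraint maps to +inf."""
    dcfg = fd.DesignConfig(
        fov=fa.FieldOfView(extent_mm=20.0, pitch_um=2000.0, depth_mm=17.0),
        rhos=np.array([10.0, 25.0]),
        grid_size=2,
    )
    ev = fd.DesignEvaluator(dcfg, fa.SimulationConfig(fc=0.25e6, fs=5e6))
    long = miura_reference(60.0, a=3.0, b=1.0, grid_size=2)
    assert np.isinf(ev(long))


def test_validation_objective_is_mean_of_squared_errors(toy3_pattern):
    from focusim.recon import ReconstructionConfig, reconstruct
    from focusim.targets import point_targets

    cfg = fa.SimulationConfig(fc=0.25e6, fs=5e6)
    fov_c = fa.FieldOfView(extent_mm=20.0, pitch_um=2000.0, depth_mm=17.0)
    fov_f = fa.FieldOfView(extent_mm=20.0, pitch_um=1000.0, depth_mm=17.0)
    Ac, Af = fa.imaging_matrix_pair(toy3_pattern, fov_c, fov_f, cfg, rhos=[10.0, 25.0])
    train = [point_targets(k + 1, fov_c, seed=k) for k in range(2)]
    rcfg = ReconstructionConfig(lr=2e-3, batch=200, patience=100, max_iter=600, seed=0)
    total = fd.validation_objective(Ac, Af, train, rcfg, seed=0)
    # recompute element-wise
    parts = []
    for k, t in enumerate(train):
        m = fa.simulate_measurement(Af, t.render(fov_f).values.ravel(), seed=k)
        rec = reconstruct(Ac, m, rcfg)
        parts.append(float(np.sum((t.values - rec.x_hat) ** 2)))
    assert total == pytest.approx(np.mean(parts), rel=1e-12)
    with pytest.raises(ValueError):
        fd.validation_objective(Ac, Af, [], rcfg)
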
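"""Inverse design: coherence objective, constraints and MADS optimization.

The design quality of a transducer is scored by the minimum-coherence
objective: the mean squared off-diagonal entry of the Gram matrix of the
column-normalized imaging matrix, scaled to [0, 100].  Low values mean the
per-pixel time responses are mutually incoherent, the property that enables
sparse single-channel image recovery.  A slower validation objective scores
a design by its mean squared reconstruction error over a synthetic training
set instead.

Optimization uses a mesh-adaptive direct search (MADS): a SEARCH step over a
Latin-hypercube sample pool (plus a variable-neighborhood perturbation step
after failed polls), and a POLL step over 2D orthogonal directions on an
adaptive mesh that coarsens on success and refines on failure.  Geometric
constraint violations are handled by the extreme barrier (infinite value,
never an incumbent); marching infeasibility gets the finite penalty 1e6.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import qmc

from .acoustics import FieldOfView, ImagingMatrix, SimulationConfig, simulate_measurement
from .frame import DEFAULT_AREA_CAP_MM2, aligned_scaled_sweep, evaluate_constraints
from .kinematics import default_driving_angles
from .pattern import MotifParameters, miura_reference, try_build_pattern

INFEASIBLE_PENALTY = 1e6


@dataclass
class DesignConfig:
    """Geometry and field-of-view settings for design evaluation."""

    fov: FieldOfView = field(
        default_factory=lambda: FieldOfView(extent_mm=20.0, pitch_um=200.0, depth_mm=17.0)
    )
    rhos: np.ndarray = field(default_factory=lambda: default_driving_angles(8))
    area_cap: float = DEFAULT_AREA_CAP_MM2
    penalty: float = INFEASIBLE_PENALTY
    grid_size: int = 5


@dataclass
class OptimizerConfig:
    """MADS settings (desk-scale defaults; the pool is sampled once)."""

    mesh_tol: float = 1e-5
    max_evals: int = 200
    time_budget_s: float = np.inf
    lhs_points: int = 100000  # candidate pool size
    lhs_evals: int = 20  # pool points actually evaluated in the SEARCH step
    vns_ratio: float = 0.8  # probability of a VNS step after a failed poll
    seed: int | None = 0


@dataclass
class OptimizationResult:
    best_params: MotifParameters
    best_value: float
    history: list  # (evaluation index, incumbent value) for improving evals
    evals_used: int
    seed: int | None


def mcp_objective(A, block: int = 512) -> float:
    """Minimum-coherence objective of a unit-column imaging matrix.

    ``100 * 2 / (P (P - 1)) * sum_{i<j} (a_i . a_j)^2`` — the squared
    off-diagonal Frobenius mass of the Gram matrix, computed blockwise so
    the full ``P x P`` Gram matrix is never materialized.  Bounded in
    [0, 100]; 0 for orthonormal columns, 100 for identical columns.
    """
    mat = A.A_tilde if isinstance(A, ImagingMatrix) else np.asarray(A, dtype=float)
    P = mat.shape[1]
    if P < 2:
        raise ValueError("need at least two columns")
    norms = np.linalg.norm(mat, axis=0)
    if np.any(norms == 0):
        raise ValueError("zero column: coherence undefined")
    if not np.allclose(norms, 1.0, atol=1e-8):
        mat = mat / norms
    total = 0.0
    for lo in range(0, P, block):
        g = mat.T @ mat[:, lo : lo + block]  # (P, b) slice of the Gram matrix
        total += float(np.sum(g * g))
    # diagonal entries are exactly 1 after normalization; halve the rest
    off = (total - P) / 2.0
    return float(100.0 * 2.0 / (P * (P - 1)) * off)


def validation_objective(
    A_recon: ImagingMatrix,
    A_sim: ImagingMatrix,
    training_set,
    cfg=None,
    snr_db: float = np.inf,
    seed: int | None = 0,
) -> float:
    """Mean squared reconstruction error over a training set of targets.

    Measurements are simulated with the fine-grid matrix ``A_sim``;
    reconstruction runs on the coarse-grid ``A_recon`` (inverse-crime
    discipline).  Each target supplies scenes rendered on both grids.
    """
    from .recon import ReconstructionConfig, reconstruct

    if not training_set:
        raise ValueError("empty training set")
    cfg = cfg or ReconstructionConfig()
    total = 0.0
    for k, target in enumerate(training_set):
        fine = target.render(A_sim.fov)
        coarse = target.render(A_recon.fov)
        meas = simulate_measurement(
            A_sim, fine.values.ravel(), snr_db=snr_db, seed=None if seed is None else seed + k
        )
        rec = reconstruct(A_recon, meas, cfg)
        total += float(np.sum((coarse.values - rec.x_hat) ** 2))
    return total / len(training_set)


class DesignEvaluator:
    """Caching full-chain design evaluation: motif vector -> objective value.

    Runs pattern marching, folding, alignment, scaling, the constraint
    check and the acoustic simulation.  Infeasible marching maps to the
    finite penalty (1e6); geometric constraint violations map to the extreme
    barrier (+inf).  Results are cached on the rounded design vector.
    """

    def __init__(
        self,
        design: DesignConfig | None = None,
        sim: SimulationConfig | None = None,
        objective: str = "mcp",
        recon_cfg=None,
        training_set=None,
        sim_fov: FieldOfView | None = None,
    ):
        self.design = design or DesignConfig()
        self.sim = sim or SimulationConfig()
        self.objective = objective
        self.recon_cfg = recon_cfg
        self.training_set = training_set
        self.sim_fov = sim_fov
        self.cache: dict = {}
        self.n_evals = 0

    def imaging_matrix(self, params: MotifParameters, fov=None) -> ImagingMatrix | None:
        from .acoustics import compute_imaging_matrix

        pattern, diag = try_build_pattern(params)
        if pattern is None:
            return None
        return compute_imaging_matrix(
            pattern,
            fov or self.design.fov,
            self.sim,
            rhos=self.design.rhos,
            area_cap=self.design.area_cap,
        )

    def __call__(self, params) -> float:
        if isinstance(params, MotifParameters):
            mp = params
        else:
            mp = MotifParameters.from_vector(np.asarray(params), self.design.grid_size)
        key = np.round(mp.as_vector(), 12).tobytes()
        if key in self.cache:
            return self.cache[key]
        value = self._evaluate(mp)
        self.cache[key] = value
        self.n_evals += 1
        return value

    def _evaluate(self, mp: MotifParameters) -> float:
        pattern, diag = try_build_pattern(mp)
        if pattern is None:
            return self.design.penalty
        try:
            states, s = aligned_scaled_sweep(
                pattern, self.design.rhos, area_cap=self.design.area_cap
            )
        except Exception:
            return self.design.penalty
        report = evaluate_constraints(states, pattern, s)
        if not report.all_passed:
            return np.inf  # extreme barrier
        from .acoustics import compute_imaging_matrix

        A = compute_imaging_matrix(
            pattern, self.design.fov, self.sim, rhos=self.design.rhos,
            area_cap=self.design.area_cap,
        )
        if len(A.zero_columns):
            return self.design.penalty
        if self.objective == "mcp":
            return mcp_objective(A)
        if self.objective == "validation":
            A_sim = compute_imaging_matrix(
                pattern, self.sim_fov, self.sim, rhos=self.design.rhos,
                area_cap=self.design.area_cap,
            )
            return validation_objective(
                A, A_sim, self.training_set, self.recon_cfg
            )
        raise ValueError(self.objective)


def lhs_sample(bounds, n: int, seed: int | None = None) -> np.ndarray:
    """Latin-hypercube sample: ``n`` points, one per stratum per dimension."""
    if n < 1:
        raise ValueError("n must be >= 1")
    bounds = np.asarray(bounds, dtype=float)
    sampler = qmc.LatinHypercube(d=len(bounds), seed=seed)
    u = sampler.random(n)
    return qmc.scale(u, bounds[:, 0], bounds[:, 1])


def default_design_bounds(grid_size: int = 5) -> np.ndarray:
    """Box bounds for the design vector: angles (10, 170) deg, lengths (0.4, 2)."""
    n_ang = 2 * (2 * grid_size - 1)
    n_len = 2 * (grid_size - 1) + 4
    return np.array([[10.0, 170.0]] * n_ang + [[0.4, 2.0]] * n_len)


def mads_optimize(
    objective,
    bounds,
    ocfg: OptimizerConfig | None = None,
    seed_point: MotifParameters | np.ndarray | None = None,
    grid_size: int = 5,
) -> OptimizationResult:
    """Mesh-adaptive direct search over the design box.

    The seed design (Miura by default) is evaluated first; a one-off
    Latin-hypercube SEARCH step explores the pool, then poll iterations
    alternate 2D orthogonal polls with occasional variable-neighborhood
    perturbations after failures.  The mesh coarsens (x4) on success and
    refines (/4) on failure; termination on mesh size, evaluation budget or
    wall-clock budget.  The incumbent sequence is non-increasing.
    """
    ocfg = ocfg or OptimizerConfig()
    bounds = np.asarray(bounds, dtype=float)
    D = len(bounds)
    lo, hi = bounds[:, 0], bounds[:, 1]
    span = hi - lo
    rng = np.random.default_rng(ocfg.seed)
    t0 = time.time()

    if seed_point is None:
        seed_point = miura_reference(60.0, grid_size=grid_size)
    x0 = seed_point.as_vector() if isinstance(seed_point, MotifParameters) else np.asarray(seed_point)

    evals = 0
    history = []
    best_x = None
    best_f = np.inf

    def ev(x):
        nonlocal evals, best_x, best_f
        x = np.clip(x, lo, hi)
        f = objective(x)
        evals += 1
        if f < best_f:
            best_f = f
            best_x = x.copy()
            history.append((evals, float(f)))
        return f

    ev(x0)

    # SEARCH: evaluate a budgeted slice of the LHS pool
    pool = lhs_sample(bounds, ocfg.lhs_points, seed=rng.integers(2**31))
    for x in pool[: min(ocfg.lhs_evals, ocfg.max_evals - evals)]:
        if evals >= ocfg.max_evals:
            break
        ev(x)

    mesh = 1.0 / 16.0
    while evals < ocfg.max_evals and mesh >= ocfg.mesh_tol:
        if time.time() - t0 > ocfg.time_budget_s:
            break
        # POLL over 2D orthogonal directions (random orthonormal basis)
        v = rng.standard_normal(D)
        v /= np.linalg.norm(v)
        B = np.eye(D) - 2.0 * np.outer(v, v)  # Householder: orthonormal columns
        step = np.sqrt(mesh)
        improved = False
        order = rng.permutation(2 * D)
        for k in order:
            if evals >= ocfg.max_evals or time.time() - t0 > ocfg.time_budget_s:
                break
            d = B[:, k % D] * (1 if k < D else -1)
            f_before = best_f
            ev(best_x + step * span * d)
            if best_f < f_before:
                improved = True
                break  # opportunistic poll
        if improved:
            mesh = min(4.0 * mesh, 1.0)
            continue
        # VNS perturbation step after a failed poll
        if rng.random() < ocfg.vns_ratio and evals < ocfg.max_evals:
            f_before = best_f
            for _ in range(2):
                if evals >= ocfg.max_evals:
                    break
                z = best_x + rng.standard_normal(D) * span * np.sqrt(mesh) * 2.0
                ev(z)
            if best_f < f_before:
                mesh = min(4.0 * mesh, 1.0)
                continue
        mesh /= 4.0

    try:
        params = MotifParameters.from_vector(best_x, grid_size)
    except ValueError:
        params = best_x  # objective over a non-motif space (e.g. test functions)
    return OptimizationResult(
        best_params=params,
        best_value=float(best_f),
        history=history,
        evals_used=evals,
        seed=ocfg.seed,
    )


@dataclass
class CorrelationHistogram:
    hist: np.ndarray
    bin_edges: np.ndarray
    variance: float
    mean: float


def sensitivity_correlation(A, bins: int = 50) -> CorrelationHistogram:
    """Histogram of absolute Pearson correlations between TIR columns.

    Characterizes the irregularity of the acoustic sensitivity field: highly
    periodic transducers (Miura) show strong correlations between pixel
    responses, incoherence-optimized ones a distribution concentrated near
    zero.  Constant columns are excluded with a warning.  Returns the
    histogram plus mean and variance of the off-diagonal |correlation|
    distribution.
    """
    mat = A.A_bar if isinstance(A, ImagingMatrix) else np.asarray(A, dtype=float)
    if mat.shape[1] < 2:
        raise ValueError("need at least two columns")
    mat = mat - mat.mean(axis=0)
    sd = np.linalg.norm(mat, axis=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"excluding {np.sum(~keep)} constant columns")
        mat = mat[:, keep]
        sd = sd[keep]
    z = mat / sd
    corr = np.abs(z.T @ z)
    iu = np.triu_indices(corr.shape[0], k=1)
    vals = np.clip(corr[iu], 0.0, 1.0)
    hist, edges = np.histogram(vals, bins=bins, range=(0.0, 1.0))
    return CorrelationHistogram(
        hist=hist, bin_edges=edges, variance=float(vals.var()), mean=float(vals.mean())
    )
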
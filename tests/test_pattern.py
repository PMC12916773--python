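"""Crease-pattern generation: Kawasaki completion, marching, boundary, MV."""

import numpy as np
import pytest

from focusim import foldio
from focusim.pattern import (
    DegenerateVertexError,
    InfeasiblePatternError,
    MotifParameters,
    build_motif,
    build_pattern,
    complete_vertex_angles,
    march_pattern,
    miura_reference,
    perturb_motif,
    rectangularize_boundary,
    try_build_pattern,
    validate_pattern,
)


@pytest.mark.parametrize(
    "pair,expected",
    [((60, 120), (60, 120, 120, 60)), ((45, 100), (45, 100, 135, 80))],
)
def test_kawasaki_completion(pair, expected):
    got = complete_vertex_angles(pair)
    assert got == pytest.approx(expected)
    assert got[0] + got[2] == pytest.approx(180.0)
    assert got[1] + got[3] == pytest.approx(180.0)


def test_degenerate_vertex_rejected():
    # equal free angles make two opposite creases collinear
    with pytest.raises(DegenerateVertexError):
        complete_vertex_angles((90, 90))


def test_angle_out_of_range():
    with pytest.raises(InfeasiblePatternError):
        complete_vertex_angles((181, 60))


def test_motif_parameter_counts():
    mp = miura_reference(60.0)
    assert mp.n_free_parameters == 30
    assert mp.free_angles.shape == (9, 2)  # nine motif vertices
    assert mp.n_lengths == 12
    motif = build_motif(mp)
    assert motif.n_vertices == 9
    # round trip through the flat design vector
    v = mp.as_vector()
    assert v.shape == (30,)
    mp2 = MotifParameters.from_vector(v, 5)
    assert np.array_equal(mp2.as_vector(), v)


def test_miura_is_homogeneous_solution(miura_pattern):
    """A uniform motif marches to congruent parallelogram panels."""
    pat = miura_pattern
    assert len(pat.faces) == 36
    assert pat.kawasaki_residual() < 1e-9
    # all internal vertices carry the same two sector values
    assert set(np.round(pat.sectors.ravel(), 9)) == {60.0, 120.0}
    # double periodicity of internal vertex positions
    pos = np.array(
        [[pat.vertices[pat.internal_vertex(i, j)] for i in range(5)] for j in range(5)]
    )
    dx = pos[:, 1:] - pos[:, :-1]
    assert np.allclose(dx, dx[:, :1], atol=1e-12)
    dy = pos[2:] - pos[:-2]
    assert np.allclose(dy, dy[:1], atol=1e-12)


def test_marching_continuity():
    """An epsilon perturbation of one angle moves vertices by O(epsilon)."""
    base = build_pattern(miura_reference(60.0))
    eps = 0.1
    mp = miura_reference(60.0)
    mp.free_angles[0, 0] += eps
    pat = build_pattern(mp)
    disp = np.abs(pat.vertices - base.vertices).max()
    assert 0 < disp < 50 * eps


def test_feasible_set_is_open():
    """Tiny (1e-6 deg) perturbations of a feasible motif stay feasible."""
    rng = np.random.default_rng(0)
    for _ in range(5):
        mp = miura_reference(60.0)
        mp.free_angles = mp.free_angles + rng.choice([-1e-6, 1e-6], mp.free_angles.shape)
        pat, diag = try_build_pattern(mp)
        assert diag.feasible, diag


def test_marching_determinism():
    mp = miura_reference(55.0)
    mp.free_angles[2] = (57.0, 122.0)
    a = build_pattern(mp)
    b = build_pattern(mp)
    assert np.array_equal(a.vertices, b.vertices)
    assert a.assignment == b.assignment


def test_extreme_sector_infeasible():
    """Sweeping a motif angle towards 180 deg must eventually fail validation."""
    failed = None
    for ang in (100.0, 130.0, 160.0, 175.0, 179.0):
        mp = miura_reference(60.0)
        mp.free_angles[0] = (ang, 20.0)
        pat, diag = try_build_pattern(mp)
        if not diag.feasible:
            failed = diag
            break
    assert failed is not None
    assert failed.failure_reason in (
        "crease-intersection",
        "marching-divergence",
        "angle-out-of-range",
        "negative-length",
    )


def test_rectangularize_boundary(miura_pattern, perturbed_pattern):
    # Miura is already rectangular: scale factors 1, idempotent
    assert np.allclose(miura_pattern.boundary_scale_factors, 1.0, atol=1e-12)
    again = rectangularize_boundary(miura_pattern)
    assert np.abs(again.vertices - miura_pattern.vertices).max() < 1e-12

    # generic pattern: corners form an axis-aligned rectangle, boundary
    # vertices lie on its sides
    pat = perturbed_pattern
    c = pat.vertices[pat.corner_vertices()]
    assert abs(c[0, 1] - c[1, 1]) < 1e-9 and abs(c[2, 1] - c[3, 1]) < 1e-9
    assert abs(c[0, 0] - c[3, 0]) < 1e-9 and abs(c[1, 0] - c[2, 0]) < 1e-9
    m = pat.grid_size + 2
    for i in range(pat.grid_size):
        assert abs(pat.vertices[pat.vid[0, i + 1]][1] - c[0, 1]) < 1e-9
        assert abs(pat.vertices[pat.vid[m - 1, i + 1]][1] - c[2, 1]) < 1e-9
    # idempotence on the generic pattern
    again = rectangularize_boundary(pat)
    assert np.abs(again.vertices - pat.vertices).max() < 1e-9


def test_mountain_valley_assignment(perturbed_pattern):
    """Maekawa |M - V| = 2 at every vertex; labels partition internal creases."""
    pat = perturbed_pattern
    counts = {}
    for (a, b), asn in zip(pat.edges, pat.assignment):
        assert asn in ("M", "V", "B")
        if asn == "B":
            continue
        for v in (int(a), int(b)):
            m, vv = counts.get(v, (0, 0))
            counts[v] = (m + (asn == "M"), vv + (asn == "V"))
    for j in range(pat.grid_size):
        for i in range(pat.grid_size):
            m, v = counts[pat.internal_vertex(i, j)]
            assert m + v == 4 and abs(m - v) == 2


def test_perturb_motif():
    mp = miura_reference(60.0)
    same = perturb_motif(mp, 0.0, seed=1)
    assert np.array_equal(same.as_vector(), mp.as_vector())
    a = perturb_motif(mp, 3.0, seed=7)
    b = perturb_motif(mp, 3.0, seed=7)
    assert np.array_equal(a.as_vector(), b.as_vector())
    # only the lower-left vertex's two free angles change
    diff = a.free_angles - mp.free_angles
    assert np.all(diff[1:] == 0) and np.all(diff[0] != 0)
    # the noise propagates through marching: every vertex above the anchored
    # bottom row moves (the canonical frame pins the bottom row itself)
    pa = build_pattern(a)
    p0 = build_pattern(mp)
    moved = np.linalg.norm(pa.vertices - p0.vertices, axis=1)
    upper = [pa.internal_vertex(i, j) for i in range(5) for j in range(1, 5)]
    assert np.all(moved[upper] > 1e-6)
    # and the multiplier compatibility propagates to every interior vertex
    assert abs(pa.mu[0, 0] - p0.mu[0, 0]) > 1e-9
    assert np.all(np.abs(pa.mu[1:, 1:] - p0.mu[1:, 1:]) > 1e-9)


def test_fold_round_trip(tmp_path, perturbed_pattern):
    path = tmp_path / "pattern.fold"
    foldio.save_pattern(perturbed_pattern, path)
    back = foldio.load_pattern(path)
    assert np.abs(back.vertices - perturbed_pattern.vertices).max() < 1e-12
    assert np.array_equal(back.edges, perturbed_pattern.edges)
    assert back.assignment == perturbed_pattern.assignment
    validate_pattern(back)


def test_small_grid_sizes():
    for n in (2, 3):
        mp = miura_reference(60.0, grid_size=n)
        assert mp.n_free_parameters == 2 * (2 * n - 1) + 2 * (n - 1) + 4
        pat = build_pattern(mp)
        assert len(pat.faces) == (n + 1) ** 2
        assert pat.kawasaki_residual() < 1e-9
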
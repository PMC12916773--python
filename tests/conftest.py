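import numpy as np
import pytest

from focusim import pattern as fp


@pytest.fixture(scope="session")
def miura_pattern():
    """Uniform Miura-ori on the default 5x5 internal grid."""
    return fp.build_pattern(fp.miura_reference(60.0))


@pytest.fixture(scope="session")
def perturbed_pattern():
    """A generic feasible (asymmetric) pattern on the 5x5 grid."""
    rng = np.random.default_rng(3)
    mp = fp.miura_reference(60.0)
    mp.free_angles = mp.free_angles + rng.normal(0, 1.5, mp.free_angles.shape)
    return fp.build_pattern(mp)


@pytest.fixture(scope="session")
def toy3_pattern():
    """Decorrelated feasible 3x3-internal-vertex pattern (fixed seed)."""
    rng = np.random.default_rng(8)
    mp = fp.miura_reference(60.0, grid_size=3)
    mp.free_angles = mp.free_angles + rng.uniform(-8, 8, mp.free_angles.shape)
    mp.bottom_lengths = mp.bottom_lengths + rng.uniform(-0.2, 0.2, 2)
    mp.left_lengths = mp.left_lengths + rng.uniform(-0.2, 0.2, 2)
    return fp.build_pattern(mp)


def spherical_linkage_fold_angles(sectors_deg, g1, signs):
    """Independent numeric oracle for a degree-4 vertex: rotation closure.

    Walks the four sectors with chain rotations ``Rx(g_i) Rz(a_i)`` and
    returns the closure residual for the candidate fold angles
    ``(g1, g2, s3 * g1, s4 * g2)`` as a function of ``g2``; the root is
    bracketed by scanning.  Returns the solved ``g2`` or None.
    """
    from scipy.optimize import brentq

    def Rx(t):
        c, s = np.cos(t), np.sin(t)
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])

    def Rz(t):
        c, s = np.cos(t), np.sin(t)
        return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])

    alphas = np.radians(sectors_deg)
    s3, s4 = signs

    def closure(g2):
        M = np.eye(3)
        for g, a in zip((g1, g2, s3 * g1, s4 * g2), alphas):
            M = M @ Rx(g) @ Rz(a)
        return M

    def f(g2):
        return closure(g2)[2, 1]

    xs = np.linspace(-np.pi + 1e-6, np.pi - 1e-6, 2001)
    vals = [f(x) for x in xs]
    for i in range(len(xs) - 1):
        if vals[i] == 0 or vals[i] * vals[i + 1] < 0:
            try:
                r = brentq(f, xs[i], xs[i + 1])
            except ValueError:
                continue
            if abs(r) > 1e-8 and np.linalg.norm(closure(r) - np.eye(3)) < 1e-9:
                return r
    return None
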
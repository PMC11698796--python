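import numpy as np
import pytest

from cellalign.geometry import ModelParams


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def rigid_params():
    """Rigid long cells at the phase-portrait working point."""
    return ModelParams(nu=2.0, gamma=0.0, r_bar=2.0)


def random_overlap_states(rng, n, r_range=(1.1, 5.0)):
    """Random (alpha, y, r) in the analysis quadrant, any region."""
    alpha = rng.uniform(1e-3, np.pi / 2 - 1e-3, n)
    r = rng.uniform(*r_range, n)
    y = np.array([rng.uniform(-np.sqrt(ri), -1e-3) for ri in r])
    return alpha, y, r


def brute_force_intersection_count(state, n_scan: int = 720) -> int:
    """Count boundary intersections by a theta-scan on cell 1 plus root
    polishing of the cell-2 implicit equation: independent of the closed
    forms."""
    import math

    from scipy.optimize import brentq

    from cellalign.geometry import boundary_point, implicit_residual

    def f(theta):
        return implicit_residual(state, 2, boundary_point(state, 1, theta))

    thetas = np.linspace(0.0, 2 * math.pi, n_scan, endpoint=False)
    vals = np.array([f(t) for t in thetas])
    roots = []
    for i in range(n_scan):
        a = thetas[i]
        b = thetas[(i + 1) % n_scan] + (2 * math.pi if i == n_scan - 1 else 0)
        fa, fb = vals[i], vals[(i + 1) % n_scan]
        if fa == 0.0:
            roots.append(a)
        elif fa * fb < 0:
            roots.append(brentq(f, a, b, xtol=1e-13))
    roots = sorted(r % (2 * math.pi) for r in roots)
    merged = []
    for r in roots:
        if not merged or min(
            abs(r - merged[-1]), 2 * math.pi - abs(r - merged[-1])
        ) > 1e-6:
            merged.append(r)
    return len(merged)
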
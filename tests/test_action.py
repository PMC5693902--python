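"""Discrete action, analytic gradients, minimization and grid refinement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from landscaper import (DiscretePath, atype_action, action_gradient,
                        discrete_action, make_fixture, minimize_action,
                        refine_action)


def fd_gradient(system, path, h=1e-7):
    """Central-difference gradient of the discrete action (interior points)."""
    base = path.points.copy()
    g = np.zeros((path.K - 1, path.N))
    for m in range(1, path.K):
        for i in range(path.N):
            step = h * max(1.0, abs(base[m, i]))
            for s, sign in ((step, 1.0), (-step, -1.0)):
                pts = base.copy()
                pts[m, i] += s
                g[m - 1, i] += sign * discrete_action(
                    system, DiscretePath(points=pts, times=path.times))
            g[m - 1, i] /= 2 * step
    return g


# ----------------------------------------------------------------------
# DiscretePath
# ----------------------------------------------------------------------

def test_straight_line_geometry():
    p = DiscretePath.straight_line([0.0, 0.0], [1.0, 2.0], K=4, T=2.0)
    assert p.K == 4 and p.N == 2
    assert p.duration == pytest.approx(2.0)
    assert np.allclose(p.times, [-1.0, -0.5, 0.0, 0.5, 1.0])
    assert np.allclose(p.points[2], [0.5, 1.0])


def test_refined_doubles_segments_preserving_geometry():
    p = DiscretePath.straight_line([0.0], [1.0], K=3, T=6.0)
    q = p.refined()
    assert q.K == 2 * p.K
    assert np.allclose(q.points[0::2], p.points)
    assert np.allclose(q.times[0::2], p.times)
    assert q.duration == pytest.approx(p.duration)


def test_path_validation():
    with pytest.raises(ValueError):
        DiscretePath(points=np.zeros((3, 1)), times=np.array([0.0, 1.0]))
    with pytest.raises(ValueError):
        DiscretePath(points=np.zeros((3, 1)), times=np.array([0.0, 1.0, 1.0]))
    with pytest.raises(ValueError):
        DiscretePath(points=np.zeros((1, 1)), times=np.array([0.0]))


# ----------------------------------------------------------------------
# Action values
# ----------------------------------------------------------------------

def test_action_zero_on_exact_euler_trajectory(double_well_1d):
    """A path satisfying x^{k} = x^{k-1} + dt f(x^{k-1}) has zero residuals."""
    dt = 0.01
    pts = [np.array([0.8])]
    for _ in range(200):
        pts.append(pts[-1] + dt * double_well_1d.drift(pts[-1]))
    path = DiscretePath(points=np.array(pts),
                        times=dt * np.arange(len(pts)))
    assert discrete_action(double_well_1d, path) == pytest.approx(0.0, abs=1e-15)


def test_action_of_frozen_path_matches_hand_value():
    """For f = -x, a stationary path at x=a has S = (T/4) a^2 exactly."""
    sys_ = make_fixture("rotational_ou", q=0.0)
    a, K, T = 1.5, 8, 2.0
    pts = np.tile([a, 0.0], (K + 1, 1))
    path = DiscretePath(points=pts, times=np.linspace(0, T, K + 1))
    # r_k = 0 - f = (a, 0); S = (1/4) sum dt * a^2 = T a^2 / 4
    assert discrete_action(sys_, path) == pytest.approx(T * a * a / 4)


def test_action_scales_with_inverse_diffusion():
    from landscaper import DynamicalSystem
    f = lambda x: -(x**3 - x)  # noqa: E731
    weak = DynamicalSystem(N=1, f=f, D=np.eye(1))
    strong = DynamicalSystem(N=1, f=f, D=4.0 * np.eye(1))
    path = DiscretePath.straight_line([-1.0], [0.0], K=20, T=4.0)
    assert discrete_action(weak, path) == pytest.approx(
        4.0 * discrete_action(strong, path))


def test_atype_action_reduces_at_zero_eps(variable_curl):
    path = DiscretePath.straight_line([0.0, 0.0], [1.0, 0.5], K=30, T=3.0)
    assert atype_action(variable_curl, path, eps=0.0) == pytest.approx(
        discrete_action(variable_curl, path))


def test_atype_action_constant_Q_equals_zero_noise(rotational_ou):
    """Delta f = 0 when D and Q are constant: eps has no effect."""
    path = DiscretePath.straight_line([0.0, 0.0], [1.0, 1.0], K=30, T=3.0)
    assert atype_action(rotational_ou, path, eps=0.7) == pytest.approx(
        discrete_action(rotational_ou, path))


def test_atype_action_requires_Q(multiplicative_system):
    path = DiscretePath.straight_line([0.0], [1.0], K=10, T=1.0)
    with pytest.raises(ValueError):
        atype_action(multiplicative_system, path, eps=0.1)


# ----------------------------------------------------------------------
# Gradient
# ----------------------------------------------------------------------

@pytest.mark.parametrize("name", ["double_well_1d", "double_well_2d",
                                  "rotational_ou", "gradient_plus_curl",
                                  "variable_curl"])
def test_gradient_matches_finite_differences(name, rng):
    sys_ = make_fixture(name)
    K = 12
    base = DiscretePath.straight_line(rng.normal(size=sys_.N),
                                      rng.normal(size=sys_.N), K=K, T=3.0)
    pts = base.points.copy()
    pts[1:-1] += 0.1 * rng.normal(size=pts[1:-1].shape)
    path = DiscretePath(points=pts, times=base.times)
    g = action_gradient(sys_, path)
    g_fd = fd_gradient(sys_, path)
    scale = np.max(np.abs(g_fd)) + 1.0
    assert np.max(np.abs(g - g_fd)) / scale < 1e-6


def test_gradient_state_dependent_diffusion(multiplicative_system, rng):
    """The finite-difference D-term of the analytic gradient is exercised."""
    base = DiscretePath.straight_line([-1.0], [1.0], K=10, T=2.0)
    pts = base.points.copy()
    pts[1:-1] += 0.2 * rng.normal(size=pts[1:-1].shape)
    path = DiscretePath(points=pts, times=base.times)
    g = action_gradient(multiplicative_system, path)
    g_fd = fd_gradient(multiplicative_system, path)
    scale = np.max(np.abs(g_fd)) + 1.0
    assert np.max(np.abs(g - g_fd)) / scale < 1e-6


def test_gradient_vanishes_at_discrete_minimum(double_well_1d):
    res = minimize_action(double_well_1d, [-1.0], [0.0], K=40, T=10.0)
    g = action_gradient(double_well_1d, res.path)
    assert np.max(np.abs(g)) < 1e-7


# ----------------------------------------------------------------------
# Minimization and refinement
# ----------------------------------------------------------------------

def test_minimize_pins_endpoints(double_well_1d):
    res = minimize_action(double_well_1d, [-1.0], [0.0], K=30, T=8.0)
    assert np.allclose(res.path.points[0], [-1.0])
    assert np.allclose(res.path.points[-1], [0.0])
    assert res.converged


def test_minimize_rejects_bad_arguments(double_well_1d):
    with pytest.raises(ValueError):
        minimize_action(double_well_1d, [0.0], [1.0], K=1)
    with pytest.raises(ValueError):
        minimize_action(double_well_1d, [0.0], [1.0], T=-1.0)
    init = DiscretePath.straight_line([0.0], [1.0], K=10, T=2.0)
    with pytest.raises(ValueError):
        minimize_action(double_well_1d, [0.0], [1.0], K=20, T=2.0, init=init)


def test_downhill_action_is_negligible(double_well_1d):
    res = refine_action(double_well_1d, [0.0], [1.0], T=20.0, K0=50)
    assert res.action >= 0.0
    assert res.action < 1e-8


def test_refine_reduces_discretization_bias():
    """Raw K=50 minima carry O(dt) bias; Richardson removes most of it."""
    sys_ = make_fixture("rotational_ou", q=1.0)
    target = 0.5  # phi(1,0) - phi(0,0) = b^2/2 with b=1
    raw = minimize_action(sys_, [0.0, 0.0], [1.0, 0.0], K=50, T=5.0)
    ref = refine_action(sys_, [0.0, 0.0], [1.0, 0.0], T=5.0, K0=50)
    assert abs(ref.action - target) < abs(raw.action - target) / 5
    assert abs(ref.action - target) / target < 5e-3
    assert ref.extrapolated
    assert ref.K_history[0] == 50 and ref.K_history[1] == 100


def test_refine_history_is_monotone_in_K(double_well_1d):
    res = refine_action(double_well_1d, [-1.0], [0.0], T=20.0, K0=25)
    assert res.K_history == [25 * 2**i for i in range(len(res.K_history))]


@settings(max_examples=10, deadline=None, derandomize=True)
@given(b=st.floats(min_value=0.5, max_value=1.5),
       q=st.floats(min_value=0.0, max_value=2.0))
def test_rotational_ou_barrier_closed_form(b, q):
    """Least action from the origin to (b, 0) equals b^2/2 for any rotation q."""
    sys_ = make_fixture("rotational_ou", q=q)
    res = refine_action(sys_, [0.0, 0.0], [b, 0.0], T=5.0, K0=60)
    assert res.action == pytest.approx(b * b / 2, rel=5e-3)
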
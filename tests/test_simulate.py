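"""Euler-Maruyama simulation, empirical potentials, Boltzmann references."""

import numpy as np
import pytest

from landscaper import (boltzmann_bin_probabilities, empirical_potential,
                        make_fixture, peak_positions, simulate)
from landscaper.simulate import EmpiricalPotential, _drift_function


def test_zero_noise_reduces_to_forward_euler(double_well_1d):
    ens = simulate(double_well_1d, "ito", eps=0.0, dt=0.01, steps=2000,
                   replicates=1, seed=0, x0=np.array([0.5]), burn_in=1900,
                   thinning=1)
    # deterministic flow from 0.5 settles into the x=1 well
    assert np.allclose(ens.samples, 1.0, atol=1e-4)


def test_seed_reproducibility(rotational_ou):
    kw = dict(eps=0.5, dt=0.01, steps=500, replicates=4)
    a = simulate(rotational_ou, "ito", seed=7, **kw)
    b = simulate(rotational_ou, "ito", seed=7, **kw)
    c = simulate(rotational_ou, "ito", seed=8, **kw)
    assert np.array_equal(a.samples, b.samples)
    assert not np.array_equal(a.samples, c.samples)


def test_ou_stationary_variance_fixes_noise_convention():
    """For dx/dt = -x + zeta with <zeta zeta> = 2 eps delta, Var(x) = eps."""
    sys_ = make_fixture("rotational_ou", q=0.0)
    eps = 0.3
    ens = simulate(sys_, "ito", eps=eps, dt=0.005, steps=40_000,
                   replicates=50, seed=11, thinning=20)
    var = ens.samples.var(axis=0)
    # O(dt) Euler bias on the variance is eps*dt/2 = 7.5e-4; MC error similar
    assert np.allclose(var, eps, rtol=0.03)


def test_simulate_argument_validation(double_well_1d):
    with pytest.raises(ValueError):
        simulate(double_well_1d, "ito", eps=0.1, dt=-1.0, steps=10)
    with pytest.raises(ValueError):
        simulate(double_well_1d, "ito", eps=0.1, dt=0.01, steps=0)
    with pytest.raises(ValueError):
        simulate(double_well_1d, "nosuch", eps=0.1, dt=0.01, steps=10)


@pytest.mark.filterwarnings("ignore:overflow:RuntimeWarning")
def test_unstable_step_raises(double_well_1d):
    # dt far beyond the stability limit of the cubic drift blows up fast
    with pytest.raises(FloatingPointError):
        simulate(double_well_1d, "ito", eps=1.0, dt=50.0, steps=200,
                 replicates=2, seed=0, x0=np.array([2.0]))


def test_atype_requires_Q(multiplicative_system):
    with pytest.raises(ValueError):
        simulate(multiplicative_system, "atype", eps=0.1, dt=0.01, steps=10)


def test_atype_correction_noop_for_constant_Q(rotational_ou, rng):
    """Constant D and Q: the A-type drift equals the bare drift."""
    f_ito = _drift_function(rotational_ou, "ito", 0.5)
    f_atype = _drift_function(rotational_ou, "atype", 0.5)
    X = rng.normal(size=(20, 2))
    assert np.allclose(f_ito(X), f_atype(X))


def test_atype_correction_shifts_variable_curl_drift(variable_curl, rng):
    """State-dependent Q: drift gains eps * Delta f = eps * (c, 0)."""
    eps = 0.7
    f_ito = _drift_function(variable_curl, "ito", eps)
    f_atype = _drift_function(variable_curl, "atype", eps)
    X = rng.normal(size=(20, 2))
    diff = f_atype(X) - f_ito(X)
    assert np.allclose(diff[:, 0], eps * 1.0, atol=1e-10)
    assert np.allclose(diff[:, 1], 0.0, atol=1e-10)


def test_stratonovich_noop_for_constant_G(rotational_ou, rng):
    f_ito = _drift_function(rotational_ou, "ito", 0.5)
    f_strat = _drift_function(rotational_ou, "stratonovich", 0.5)
    X = rng.normal(size=(10, 2))
    assert np.allclose(f_ito(X), f_strat(X))


def test_stratonovich_correction_multiplicative(multiplicative_system):
    """G = sqrt(1+x^2/2): correction is eps * G G' = eps * x/2."""
    eps = 0.4
    f_strat = _drift_function(multiplicative_system, "stratonovich", eps)
    x = np.array([[1.2]])
    expected = -1.2 + eps * 1.2 / 2
    assert f_strat(x)[0, 0] == pytest.approx(expected, abs=1e-6)


# ----------------------------------------------------------------------
# Empirical potential
# ----------------------------------------------------------------------

@pytest.fixture(scope="module")
def ou_ensemble():
    sys_ = make_fixture("rotational_ou", q=1.0)
    return sys_, simulate(sys_, "atype", eps=0.5, dt=0.005, steps=20_000,
                          replicates=100, seed=21, thinning=20)


def test_empirical_potential_shape_and_shift(ou_ensemble):
    _, ens = ou_ensemble
    pot = empirical_potential(ens, [(-3, 3), (-3, 3)], bins=21)
    assert pot.values.shape == (21, 21)
    assert np.nanmin(pot.values) == pytest.approx(0.0)
    assert np.all(np.isnan(pot.values[~pot.occupied]))
    df = pot.to_dataframe(min_count=5)
    assert set(df.columns) == {"x1", "x2", "count", "potential"}
    assert (df["count"] >= 5).all()


def test_empirical_potential_recovers_quadratic_phi(ou_ensemble):
    """A-type sampling of the rotational OU reproduces phi = |x|^2/2."""
    sys_, ens = ou_ensemble
    pot = empirical_potential(ens, [(-3, 3), (-3, 3)], bins=21)
    ref = boltzmann_bin_probabilities(sys_, [(-3, 3), (-3, 3)], bins=21,
                                      eps=ens.eps)
    well = pot.counts >= 300
    emp = pot.values[well]
    theo = -ens.eps * np.log(ref[well])
    theo -= theo.min() - emp.min()
    assert np.mean(np.abs(emp - theo)) < 0.05 * ens.eps


def test_empirical_potential_rejects_empty_box(ou_ensemble):
    _, ens = ou_ensemble
    with pytest.raises(ValueError):
        empirical_potential(ens, [(50, 60), (50, 60)], bins=5)


def test_boltzmann_bin_probabilities_normalized(rotational_ou):
    p = boltzmann_bin_probabilities(rotational_ou, [(-3, 3), (-3, 3)],
                                    bins=15, eps=1.0)
    assert p.shape == (15, 15)
    assert p.sum() == pytest.approx(1.0)
    # symmetric potential: distribution symmetric under both reflections
    assert np.allclose(p, p[::-1, :], atol=1e-12)
    assert np.allclose(p, p[:, ::-1], atol=1e-12)


def test_boltzmann_requires_analytic_potential(toggle_switch_spec):
    from landscaper import build_hill_system
    sys_ = build_hill_system(toggle_switch_spec)
    with pytest.raises(ValueError):
        boltzmann_bin_probabilities(sys_, [(0, 3), (0, 3)], bins=5, eps=1.0)


def test_peak_positions_synthetic_grid():
    """Two hand-built minima on a 5x5 grid are found; plateaus are not."""
    edges = [np.linspace(0, 5, 6), np.linspace(0, 5, 6)]
    vals = np.full((5, 5), 2.0)
    vals[1, 1] = 0.0
    vals[3, 3] = 0.5
    counts = np.full((5, 5), 10, dtype=int)
    pot = EmpiricalPotential(edges=edges, values=vals, counts=counts, eps=1.0)
    peaks = peak_positions(pot)
    assert peaks.shape == (2, 2)
    assert np.allclose(peaks, [[1.5, 1.5], [3.5, 3.5]])
    # a flat landscape has no strict minima
    flat = EmpiricalPotential(edges=edges, values=np.zeros((5, 5)),
                              counts=counts, eps=1.0)
    assert peak_positions(flat).shape == (0, 2)


def test_peak_positions_respect_min_count(ou_ensemble):
    """The single OU well sits at the origin bin of the empirical potential."""
    _, ens = ou_ensemble
    pot = empirical_potential(ens, [(-3, 3), (-3, 3)], bins=21)
    peaks = peak_positions(pot, min_count=50)
    # grid spacing is 6/21; the deepest minimum must be the central bin
    assert any(np.linalg.norm(p) < 6 / 21 for p in peaks)
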
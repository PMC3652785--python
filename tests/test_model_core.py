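"""Unit and property tests for the model definitions and phase-plane
geometry."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gnrhsync.model_core import (
    CellParams,
    CellState,
    NetworkParams,
    NetworkState,
    cell_preset,
    cell_rhs,
    critical_manifold_y,
    equilibrium,
    fold_x,
    network_preset,
    network_rhs,
    phi_fall,
    phi_rise,
    phi_sigma,
    phi_syn,
    _network_rhs_flat,
)


# ---------------------------------------------------------------------------
# coupling functions
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "ca, mu, ca0, expected",
    [
        (0.0, 2.4, 500.0, 0.0),          # zero numerator
        (500.0, 2.4, 500.0, 1.2),        # half-saturation gives mu/2
        (100.0, 2.4, 500.0, 0.4),        # 2.4*100/600
    ],
)
def test_phi_fall_values(ca, mu, ca0, expected):
    assert phi_fall(ca, mu, ca0) == pytest.approx(expected, abs=1e-12)


def test_phi_fall_domain_errors():
    with pytest.raises(ValueError):
        phi_fall(-1.0, 2.4, 500.0)
    with pytest.raises(ValueError):
        phi_fall(1.0, 2.4, 0.0)


def test_phi_rise_values():
    # sigmoid midpoint is lam/2
    assert phi_rise(-0.45, 175.0, 4.5, -0.45) == pytest.approx(87.5)
    # saturation from below at 0
    assert phi_rise(-1e3, 175.0, 4.5, -0.45) == pytest.approx(0.0, abs=1e-12)
    # direct evaluation: 175 / (1 + e^{-8.775})
    expected = 175.0 / (1.0 + math.exp(-4.5 * (1.5 + 0.45)))
    assert phi_rise(1.5, 175.0, 4.5, -0.45) == pytest.approx(expected, rel=1e-12)


def test_activation_sigmoid_values():
    assert phi_syn(60.0, 5.0, 60.0) == pytest.approx(0.5)
    assert phi_sigma(0.0, 30.0) == pytest.approx(0.5)
    assert phi_syn(61.0, 5.0, 60.0) == pytest.approx(1.0 / (1.0 + math.exp(-5.0)), rel=1e-12)


@given(
    slope=st.floats(0.1, 1e6),
    centre=st.floats(-100.0, 100.0),
)
@settings(max_examples=50, derandomize=True)
def test_sigmoids_monotone_and_bounded(slope, centre):
    grid = np.linspace(centre - 50, centre + 50, 201)
    s = phi_syn(grid, slope, centre)
    assert np.all(np.diff(s) >= 0) and np.all((s >= 0) & (s <= 1))
    f = phi_sigma(grid - centre, slope)
    assert np.all(np.diff(f) >= 0) and np.all((f >= 0) & (f <= 1))


@given(mu=st.floats(0.1, 10.0), ca0=st.floats(1.0, 1e4), lam=st.floats(1.0, 1e3))
@settings(max_examples=50, derandomize=True)
def test_phi_fall_rise_bounds(mu, ca0, lam):
    ca = np.linspace(0.0, 1e5, 301)
    f = phi_fall(ca, mu, ca0)
    assert np.all(np.diff(f) >= 0) and np.all((f >= 0) & (f <= mu))
    assert np.all(np.diff(f)[ca[:-1] < 10 * ca0] > 0)  # strict short of saturation
    x = np.linspace(-20.0, 20.0, 301)
    r = phi_rise(x, lam, 4.5, -0.45)
    assert np.all(np.diff(r) >= 0) and np.all((r >= 0) & (r <= lam))
    mid = np.abs(x[:-1] + 0.45) < 3
    assert np.all(np.diff(r)[mid] > 0)


# ---------------------------------------------------------------------------
# right-hand sides
# ---------------------------------------------------------------------------


def test_cell_rhs_on_ca_nullcline():
    p = cell_preset()
    x = 0.3
    ca = p.tauCa * float(phi_rise(x, p.lam, p.rhoCa, p.xon)) + p.Cabas
    d = cell_rhs(CellState(x, 0.0, ca), p)
    assert d.Ca == pytest.approx(0.0, abs=1e-10)


def test_cell_rhs_hand_evaluated_at_origin():
    p = cell_preset()
    d = cell_rhs(CellState(0.0, 0.0, 0.0), p)
    # x' = tau*(0 + 0 - 0 - phi_fall(0)) = 0
    assert d.x == pytest.approx(0.0, abs=1e-12)
    # y' = tau*eps*k*(0 + 0 + a2) = 37*0.06*0.8
    assert d.y == pytest.approx(37.0 * 0.06 * 0.8, rel=1e-12)
    # Ca' = tau*eps*(phi_rise(0) + 100/2)
    pr0 = 175.0 / (1.0 + math.exp(-4.5 * 0.45))
    assert d.Ca == pytest.approx(37.0 * 0.06 * (pr0 + 50.0), rel=1e-12)


def test_cell_rhs_vanishes_at_equilibrium():
    p = cell_preset()
    eq = equilibrium(p)
    d = cell_rhs(eq, p)
    assert abs(d.x) < 1e-8 and abs(d.y) < 1e-8 and abs(d.Ca) < 1e-8


def test_cell_rhs_rejects_negative_drive_and_nonfinite_state():
    p = cell_preset()
    with pytest.raises(ValueError):
        cell_rhs(CellState(0.0, 0.0, 0.0), p, drive=-1.0)
    with pytest.raises(ValueError):
        CellState(np.nan, 0.0, 0.0)


def test_network_rhs_matches_scalar_cells():
    """N=2 network derivative equals two independent cell derivatives plus
    the sigma row, with the coupling drive evaluated by hand."""
    rng = np.random.default_rng(0)
    p = network_preset("table2-full-sync", N=2, kj=np.array([0.9, 1.1]))
    cells = [
        CellState(*rng.normal(size=2), rng.uniform(50, 400)) for _ in range(2)
    ]
    sigma = 59.0
    state = NetworkState(cells=cells, sigma=sigma)
    d = network_rhs(state, p)
    drive = float(phi_syn(sigma, p.rho_syn, p.sigma_on))
    for j, c in enumerate(cells):
        pj = p.cell.replace(k=float(p.kj[j]))
        dj = cell_rhs(c, pj, drive=float(p.etaj[j]) * drive)
        assert d.cells[j].x == pytest.approx(dj.x, rel=1e-12)
        assert d.cells[j].y == pytest.approx(dj.y, rel=1e-12)
        assert d.cells[j].Ca == pytest.approx(dj.Ca, rel=1e-12)
    mean_ca = np.mean([c.Ca for c in cells])
    expected_sigma = p.cell.tau * (
        p.delta * p.cell.eps * sigma
        - p.gamma * (sigma - p.sigma0) * float(phi_sigma(mean_ca - p.Cadesyn, p.rho_sigma))
    )
    assert d.sigma == pytest.approx(expected_sigma, rel=1e-12)


def test_network_rhs_decoupled_limit():
    """With eta=0 and sigma far below threshold, each cell's derivative is
    the isolated cell RHS and sigma' is its linear growth term."""
    rng = np.random.default_rng(1)
    p = network_preset("table2-full-sync", N=1, etaj=np.zeros(1))
    c = CellState(*rng.normal(size=2), 120.0)
    state = NetworkState(cells=[c], sigma=0.2)
    d = network_rhs(state, p)
    iso = cell_rhs(c, p.cell)
    assert d.cells[0].x == pytest.approx(iso.x, rel=1e-12)
    assert d.cells[0].Ca == pytest.approx(iso.Ca, rel=1e-12)
    assert d.sigma == pytest.approx(p.cell.tau * p.delta * p.cell.eps * 0.2, rel=1e-6)


def test_network_rhs_reset_term_vanishes_at_sigma0():
    """At sigma = sigma0 the reset factor is zero even with phi_sigma fully
    active, so sigma' = tau*delta*eps*sigma0 > 0."""
    p = network_preset("table2-full-sync", N=1)
    state = NetworkState(cells=[CellState(2.0, 0.0, 450.0)], sigma=p.sigma0)
    d = network_rhs(state, p)
    assert d.sigma == pytest.approx(p.cell.tau * p.delta * p.cell.eps * p.sigma0, rel=1e-9)
    assert d.sigma > 0


def test_network_rhs_heaviside_limit():
    """At slope 1e6 the smooth sigmoids agree with the Heaviside variant to
    1e-6 away from the switching thresholds."""
    rng = np.random.default_rng(2)
    p = network_preset("table2-full-sync", N=5).replace(rho_syn=1e6, rho_sigma=1e6)
    for _ in range(20):
        s = np.concatenate([
            rng.normal(size=5), rng.normal(size=5), rng.uniform(50, 340, 5),
            [rng.uniform(0.1, 120)],
        ])
        # keep clear of the sigma_on and Cadesyn switching surfaces
        if abs(s[-1] - p.sigma_on) < 1e-4 or abs(s[10:15].mean() - p.Cadesyn) < 1e-4:
            continue
        smooth = _network_rhs_flat(s, p)
        heavi = _network_rhs_flat(s, p, heaviside=True)
        assert np.max(np.abs(smooth - heavi)) < 1e-6


def test_network_rhs_dimension_mismatch():
    p = network_preset("table2-full-sync", N=3)
    state = NetworkState(cells=[CellState(0, 0, 100)] * 2, sigma=1.0)
    with pytest.raises(ValueError):
        network_rhs(state, p)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


def test_critical_manifold_values():
    p = cell_preset()
    assert critical_manifold_y(0.0, 0.0, p) == pytest.approx(0.0)
    assert critical_manifold_y(1.0, 0.0, p) == pytest.approx(3.0)
    xf = -2.0 / math.sqrt(3.0)
    expected = 4 * xf - xf**3 - 0.4  # phi_fall(100) = 0.4
    assert critical_manifold_y(xf, 100.0, p) == pytest.approx(expected, rel=1e-12)


def test_fold_positions():
    xm, xp = fold_x()
    assert xm == pytest.approx(-2.0 / math.sqrt(3.0), rel=1e-14)
    assert xp == -xm
    # curvature 4 - 3x^2 changes sign at each fold
    for xf in (xm, xp):
        assert (4 - 3 * (xf - 1e-6) ** 2) * (4 - 3 * (xf + 1e-6) ** 2) < 0


def test_equilibrium_2d_cubic_oracle():
    """With Ca frozen at 100 nM the equilibrium x solves the depressed
    cubic x^3 + 6x + 8.4 = 0; compare the model's residual root against
    numpy's polynomial roots."""
    roots = np.roots([1.0, 0.0, 6.0, 8.4])
    real = roots[np.isclose(roots.imag, 0.0)].real
    assert real.size == 1
    p = cell_preset()
    # same equation expressed through the model's residual with Ca pinned
    from scipy.optimize import brentq

    def res(x):
        y = critical_manifold_y(x, 100.0, p)
        return p.a0 * x + p.a1 * y + p.a2

    x = brentq(res, -3, 3, xtol=1e-13)
    assert x == pytest.approx(real[0], abs=1e-9)
    assert x == pytest.approx(-1.1478, abs=5e-4)


def test_equilibrium_full_3d_location():
    p = cell_preset()
    eq = equilibrium(p)
    xm, _ = fold_x()
    # excitable/MMO regime: rest point within O(eps) of the lower fold,
    # and it moves onto the attracting left sheet for large mu (steady)
    assert abs(eq.x - xm) < 0.05
    assert equilibrium(p.replace(mu=3.0)).x < xm
    assert equilibrium(p.replace(mu=2.0)).x > equilibrium(p.replace(mu=2.4)).x
    # residuals of all three defining equations
    assert p.a0 * eq.x + p.a1 * eq.y + p.a2 == pytest.approx(0.0, abs=1e-10)
    assert eq.y == pytest.approx(float(critical_manifold_y(eq.x, eq.Ca, p)), abs=1e-10)
    assert eq.Ca == pytest.approx(
        p.tauCa * float(phi_rise(eq.x, p.lam, p.rhoCa, p.xon)) + p.Cabas, abs=1e-10
    )


def test_equilibrium_strong_drive_right_branch():
    """A strong coupling drive moves the rest point to the right sheet."""
    p = cell_preset()
    eq = equilibrium(p, drive=3.0)
    assert eq.x > 2.0 / math.sqrt(3.0)


def test_equilibrium_uniqueness_sign_change():
    from gnrhsync.model_core import _equilibrium_x_residual

    p = cell_preset()
    xs = np.linspace(-3, 3, 1201)
    vals = np.array([_equilibrium_x_residual(x, p, 0.0) for x in xs])
    assert np.sum(np.diff(np.sign(vals)) != 0) == 1


# ---------------------------------------------------------------------------
# parameter validation
# ---------------------------------------------------------------------------


def test_cellparams_validation():
    with pytest.raises(ValueError):
        CellParams(a1=0.1)           # a1 must be negative
    with pytest.raises(ValueError):
        CellParams(a1=-0.5)          # a0/|a1| must exceed 4
    with pytest.raises(ValueError):
        CellParams(eps=0.0)


def test_networkparams_validation():
    cell = cell_preset()
    ok = dict(cell=cell, N=2, kj=np.ones(2), etaj=np.ones(2))
    NetworkParams(**ok)
    with pytest.raises(ValueError):
        NetworkParams(**{**ok, "kj": np.ones(3)})
    with pytest.raises(ValueError):
        NetworkParams(**{**ok, "sigma0": 70.0})  # sigma0 >= sigma_on
    with pytest.raises(ValueError):
        NetworkParams(**{**ok, "gamma": 0.0})


def test_network_state_array_round_trip():
    rng = np.random.default_rng(3)
    cells = [CellState(*rng.normal(size=3)) for _ in range(4)]
    ns = NetworkState(cells=cells, sigma=1.5)
    arr = ns.to_array()
    back = NetworkState.from_array(arr, 4)
    assert np.allclose(back.to_array(), arr)
    with pytest.raises(ValueError):
        NetworkState.from_array(arr[:-1], 4)
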
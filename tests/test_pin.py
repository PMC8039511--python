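"""PIN trafficking: steady states, timescales, conservation, memory law."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import solve_ivp

from gravipin import (
    MembraneModel,
    PinParameters,
    PinState,
    StatocyteGeometry,
    derive_regime,
    limiting_pool_timescales,
    pile_cross_section,
    pin_rhs,
    pin_steady_state,
    pin_timescales,
)

rates = st.floats(0.01, 10.0)
angles = st.floats(0.0, 180.0)


def dimensional_rhs_oracle(pin_0, pin_1, part, k_on_0, k_on_1, k_off_0, k_off_1,
                           N_tot, W):
    """Brute-force dimensional trafficking rates, written straight from the
    endocytosis/exocytosis balance with an explicit cytoplasmic pool of
    volume W*S: d[PIN]_i/dt = -k_off_i [PIN]_i + k_on_i [PIN]_vol."""
    S = part.S
    pin_vol = (N_tot - (part.S0 * pin_0 + part.S1 * pin_1)) / (W * S)
    return (-k_off_0 * pin_0 + k_on_0 * pin_vol,
            -k_off_1 * pin_1 + k_on_1 * pin_vol)


@given(k_off_0=rates, k_off_1=rates, kappa_0=rates, kappa_1=rates,
       theta=angles, u0=st.floats(0.0, 3.0), u1=st.floats(0.0, 3.0))
def test_rhs_matches_dimensional_oracle(k_off_0, k_off_1, kappa_0, kappa_1,
                                        theta, u0, u1):
    """The nondimensional two-class ODE equals the dimensional mass-action
    form after u_i = [PIN]_i S / N_tot, kappa_i = k_on_i / W."""
    geom = StatocyteGeometry()
    part = pile_cross_section(geom, theta)
    p = PinParameters(k_off_0, k_off_1, kappa_0, kappa_1)
    du0, du1 = pin_rhs(PinState(u0, u1, 0.0), part, p)

    W, N_tot = 7.0, 3.0  # arbitrary dimensional anchors
    S = part.S
    pin_0, pin_1 = u0 * N_tot / S, u1 * N_tot / S
    d0, d1 = dimensional_rhs_oracle(pin_0, pin_1, part, kappa_0 * W,
                                    kappa_1 * W, k_off_0, k_off_1, N_tot, W)
    assert du0 == pytest.approx(d0 * S / N_tot, rel=1e-12, abs=1e-12)
    assert du1 == pytest.approx(d1 * S / N_tot, rel=1e-12, abs=1e-12)


@given(k_off_0=rates, k_off_1=rates, kappa_0=rates, kappa_1=rates, theta=angles)
def test_steady_state_ratio_is_R(k_off_0, k_off_1, kappa_0, kappa_1, theta):
    """u1/u0 = R at steady state regardless of geometry and pool number."""
    part = pile_cross_section(StatocyteGeometry(), theta)
    p = PinParameters(k_off_0, k_off_1, kappa_0, kappa_1)
    ss = pin_steady_state(p, part)
    assert ss.u1 / ss.u0 == pytest.approx(derive_regime(p).R, rel=1e-12)
    du0, du1 = pin_rhs(ss, part, p)
    assert abs(du0) < 1e-12 and abs(du1) < 1e-12


def test_symmetric_rates_give_equal_classes(geom):
    part = pile_cross_section(geom, 45.0)
    p = PinParameters(0.3, 0.3, 1.1, 1.1)
    ss = pin_steady_state(p, part)
    assert ss.u0 == pytest.approx(ss.u1, rel=1e-14)


def test_steady_state_matches_long_integration(geom):
    part = pile_cross_section(geom, 60.0)
    p = PinParameters(0.2, 0.5, 0.8, 2.4)
    ss = pin_steady_state(p, part)
    _, tau2 = pin_timescales(p, part)

    def rhs(t, y):
        return pin_rhs(PinState(y[0], y[1], 0.0), part, p)

    sol = solve_ivp(rhs, (0.0, 50.0 * tau2), [0.0, 0.0], method="BDF",
                    rtol=1e-12, atol=1e-14)
    assert sol.y[0, -1] == pytest.approx(ss.u0, abs=1e-8)
    assert sol.y[1, -1] == pytest.approx(ss.u1, abs=1e-8)


def test_conservation_along_trajectory(geom):
    """S0 u0 + S1 u1 + S*pool is invariant along the trafficking flow."""
    part = pile_cross_section(geom, 30.0)
    p = PinParameters(0.4, 0.1, 2.0, 5.0)

    def rhs(t, y):
        return pin_rhs(PinState(y[0], y[1], 0.0), part, p)

    sol = solve_ivp(rhs, (0.0, 40.0), [0.7, 0.1], rtol=1e-10, atol=1e-12,
                    dense_output=True)
    surf = part.S0 * sol.y[0] + part.S1 * sol.y[1]
    pool = part.S * (1.0 - surf / part.S)  # definition of the pool fraction
    total = surf + pool
    assert np.allclose(total, total[0], rtol=1e-12)


@given(k_off_0=rates, k_off_1=rates, kappa_0=rates, kappa_1=rates, theta=angles)
def test_timescales_match_numerical_jacobian(k_off_0, k_off_1, kappa_0,
                                             kappa_1, theta):
    """(tau_1, tau_2) equal the inverse eigen-rates of a finite-difference
    Jacobian of pin_rhs."""
    part = pile_cross_section(StatocyteGeometry(), theta)
    p = PinParameters(k_off_0, k_off_1, kappa_0, kappa_1)
    tau1, tau2 = pin_timescales(p, part)

    eps = 1e-7
    base = np.array(pin_rhs(PinState(0.3, 0.4, 0.0), part, p))
    J = np.empty((2, 2))
    for j, (du0, du1) in enumerate([(eps, 0.0), (0.0, eps)]):
        pert = np.array(pin_rhs(PinState(0.3 + du0, 0.4 + du1, 0.0), part, p))
        J[:, j] = (pert - base) / eps
    lam = np.sort(np.linalg.eigvals(J).real)
    assert -1.0 / lam[0] == pytest.approx(tau1, rel=1e-5)
    assert -1.0 / lam[1] == pytest.approx(tau2, rel=1e-5)


def test_exocytosis_biased_coupling_tau2(geom):
    """Equal detachment rates: the slow PIN time is exactly 1/k_off."""
    part = pile_cross_section(geom, 45.0)
    k = 0.31
    p = PinParameters(k, k, 50.0, 1250.0)  # limiting pool, R = 25
    _, tau2 = pin_timescales(p, part)
    assert tau2 == pytest.approx(1.0 / k, rel=1e-3)
    tau1_cf, tau2_cf = limiting_pool_timescales(p, part)
    assert tau2_cf == pytest.approx(1.0 / k, rel=1e-12)


def test_endocytosis_biased_coupling_controlled_by_fastest_rate(geom):
    """k_off_0 >> k_off_1 with equal kappa: the slow time follows the
    FASTEST detachment rate k_off_0 (limiting pool), not 1/k_off_1."""
    part = pile_cross_section(geom, 45.0)
    k_off_0, k_off_1 = 2.0, 2.0 / 25.0
    kappa = 500.0  # deep limiting pool
    p = PinParameters(k_off_0, k_off_1, kappa, kappa)
    _, tau2 = pin_timescales(p, part)
    _, tau2_cf = limiting_pool_timescales(p, part)
    # closed form carries O(k_off S / (kappa S_i)) corrections
    assert tau2 == pytest.approx(tau2_cf, rel=5e-3)
    # within the geometric factor (1 + S0/S1) of 1/k_off_0 ...
    factor = 1.0 + part.S0 / part.S1
    assert 1.0 / k_off_0 < tau2 < 1.05 * factor / k_off_0
    # ... and decades away from 1/k_off_1
    assert tau2 < 0.2 / k_off_1


def test_derive_regime_and_reduced_roundtrip(geom):
    p = PinParameters(0.5, 0.5, 0.2, 5.0)
    reg = derive_regime(p)
    assert reg.R == pytest.approx(25.0)
    assert reg.P == pytest.approx(0.1)

    p2 = PinParameters.from_reduced(R=25.0, P=1e-4, tau_pin=13.0)
    reg2 = derive_regime(p2)
    assert reg2.R == pytest.approx(25.0)
    assert reg2.P == pytest.approx(1e-4)
    part = pile_cross_section(geom, 45.0)
    _, tau2 = pin_timescales(p2, part)
    assert tau2 == pytest.approx(13.0, rel=1e-3)


@given(theta=angles, P=st.floats(1e-6, 1e3))
def test_pool_number_identity(theta, P):
    """N_tot/(S0 [PIN]0 + S1 [PIN]1) = 1 + P [(S1/S) + S0/(S R)]^{-1} at
    steady state; P >> 1 gives pool ~ 1 (infinite pool), P << 1 puts all
    PIN on the membrane (limiting pool)."""
    part = pile_cross_section(StatocyteGeometry(), theta)
    R = 25.0
    p = PinParameters.from_reduced(R=R, P=P, tau_pin=1.0)
    ss = pin_steady_state(p, part)
    membrane = part.S0 * ss.u0 + part.S1 * ss.u1
    lhs = part.S / membrane  # N_tot/(surface total) in u-units
    rhs = 1.0 + P / (part.S1 / part.S + part.S0 / (part.S * R))
    assert lhs == pytest.approx(rhs, rel=1e-10)


def test_pool_regimes(geom):
    part = pile_cross_section(geom, 45.0)
    big = pin_steady_state(PinParameters.from_reduced(25.0, 1e3, 1.0), part)
    assert big.pool == pytest.approx(1.0, abs=2e-3)
    small = pin_steady_state(PinParameters.from_reduced(25.0, 1e-6, 1.0), part)
    assert part.S0 * small.u0 + part.S1 * small.u1 == pytest.approx(
        part.S, rel=1e-5)


class TestMembraneModel:
    def test_patch_scheme_memory_law(self, geom, pin_reduced):
        """After a tilt, the lateral asymmetry follows the single-exponential
        memory law asym(t) = asym_steady (1 - exp(-t/tau_PIN)) in the
        limiting-pool, exocytosis-biased case."""
        p = PinParameters.from_reduced(R=25.0, P=1e-7, tau_pin=13.0)
        m = MembraneModel(p, pile_cross_section(geom, 0.0), scheme="patch")
        part45 = pile_cross_section(geom, 45.0)
        m.reassign(part45)
        ss = pin_steady_state(p, part45)
        asym_inf = (ss.u1 - ss.u0) * (part45.S1_r - part45.S1_l)
        for t in [0.5, 2.0, 6.5, 13.0, 39.0]:
            law = asym_inf * (1.0 - np.exp(-t / 13.0))
            assert m.asymmetry_at(t) == pytest.approx(law, rel=2e-4)

    def test_patch_conserves_membrane_total_across_switch(self, geom,
                                                          pin_reduced):
        m = MembraneModel(pin_reduced, pile_cross_section(geom, 0.0))
        before = m.totals()
        m.reassign(pile_cross_section(geom, 70.0))
        assert m.totals() == pytest.approx(before, rel=1e-12)

    def test_pooled_scheme_jumps_to_new_steady(self, geom, pin_reduced):
        """The class-pooled bookkeeping responds essentially instantly
        (the documented reason it is not the default)."""
        m = MembraneModel(pin_reduced, pile_cross_section(geom, 0.0),
                          scheme="pooled")
        part45 = pile_cross_section(geom, 45.0)
        m.reassign(part45)
        ss = pin_steady_state(pin_reduced, part45)
        asym_inf = (ss.u1 - ss.u0) * (part45.S1_r - part45.S1_l)
        # within a couple of fast times tau_1 it has already converged
        assert m.asymmetry_at(0.05) == pytest.approx(asym_inf, rel=1e-3)

    def test_schemes_agree_at_long_times(self, geom, pin_reduced):
        part45 = pile_cross_section(geom, 45.0)
        mp = MembraneModel(pin_reduced, pile_cross_section(geom, 0.0), "patch")
        mq = MembraneModel(pin_reduced, pile_cross_section(geom, 0.0), "pooled")
        mp.reassign(part45)
        mq.reassign(part45)
        t = 20 * 13.0
        assert mp.asymmetry_at(t) == pytest.approx(mq.asymmetry_at(t), rel=1e-6)

    def test_propagation_matches_ode_integration(self, geom):
        """Exact compartment propagation equals a brute-force stiff ODE
        solve of the same affine system."""
        p = PinParameters(0.7, 0.15, 3.0, 20.0)
        m = MembraneModel(p, pile_cross_section(geom, 0.0))
        part = pile_cross_section(geom, 55.0)
        m.reassign(part)
        u0 = m._u.copy()
        L, cls, S = m._lengths, m._classes, m.S
        koff = np.where(cls == 1, p.k_off_1, p.k_off_0)
        kap = np.where(cls == 1, p.kappa_1, p.kappa_0)

        def rhs(t, u):
            pool = 1.0 - (L @ u) / S
            return -koff * u + kap * pool

        sol = solve_ivp(rhs, (0.0, 7.3), u0, method="Radau", rtol=1e-11,
                        atol=1e-13)
        np.testing.assert_allclose(m.u_at(7.3), sol.y[:, -1], rtol=1e-7)

    def test_invalid_scheme(self, geom, pin_reduced):
        with pytest.raises(ValueError):
            MembraneModel(pin_reduced, pile_cross_section(geom, 0.0), "bogus")
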
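"""Flux kernels: water, electrodiffusion, coupling, pumps, torque."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nephroflux.constants import CONSTANTS
from nephroflux.fluxes import (
    MembraneSpec,
    TorqueParams,
    TransporterSpec,
    atpase_flux,
    compliant_radius,
    convective_flux,
    coupled_flux,
    electrodiffusive_flux,
    log_mean_concentration,
    microvillous_torque,
    torque_scale,
    total_solute_flux,
    water_flux,
)
from nephroflux import solutes as S


def _membrane(area=1.0, Lp=1.0, sigma=1.0, perm=None):
    p = np.zeros(15)
    if perm:
        for k, v in perm.items():
            p[k] = v
    return MembraneSpec(("a", "b"), area, Lp, sigma, p)


# -- water ------------------------------------------------------------------


def test_water_flux_zero_without_driving_force():
    m = _membrane()
    assert water_flux(m, np.zeros(15), 0.0) == 0.0


def test_water_flux_ignores_osmosis_when_fully_leaky():
    m = _membrane(sigma=0.0)
    dC = np.zeros(15)
    dC[S.NA] = 25.0
    assert water_flux(m, dC, 0.0) == 0.0


def test_water_flux_direct_evaluation_single_solute():
    m = _membrane(area=1.0, Lp=1.0, sigma=1.0)
    dC = np.zeros(15)
    dC[S.UREA] = 1.0  # 1 mM far-minus-near difference
    assert water_flux(m, dC, 0.0) == pytest.approx(CONSTANTS.RT_osm, rel=1e-12)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(dc=st.floats(-50, 50), dp=st.floats(-20, 20))
def test_water_flux_antisymmetric(dc, dp):
    m = _membrane(area=0.3, Lp=2e-7, sigma=0.8)
    dC = np.zeros(15)
    dC[S.NA] = dc
    assert water_flux(m, dC, dp) == pytest.approx(
        -water_flux(m, -dC, -dp), rel=1e-12, abs=1e-30
    )


# -- log mean ---------------------------------------------------------------


def test_log_mean_limit_and_value():
    assert log_mean_concentration(10.0, 10.0) == pytest.approx(10.0)
    assert log_mean_concentration(100.0, 50.0) == pytest.approx(
        50.0 / np.log(2.0), rel=1e-12
    )


@settings(deadline=None, max_examples=50, derandomize=True)
@given(a=st.floats(1e-3, 1e3), b=st.floats(1e-3, 1e3))
def test_log_mean_symmetric_and_bounded(a, b):
    m = log_mean_concentration(a, b)
    assert m == pytest.approx(log_mean_concentration(b, a), rel=1e-12)
    assert min(a, b) - 1e-12 <= m <= max(a, b) + 1e-12


def test_log_mean_rejects_nonpositive():
    with pytest.raises(ValueError):
        log_mean_concentration(-1.0, 2.0)


# -- GHK --------------------------------------------------------------------


def test_ghk_uncharged_is_ficks_law():
    assert electrodiffusive_flux(0, 1.0, 12.0, 2.0, 50.0) == pytest.approx(10.0)


@pytest.mark.parametrize("ca,cb", [(144.0, 10.0), (5.0, 140.0), (30.0, 30.0)])
def test_ghk_converges_to_fick_as_potential_vanishes(ca, cb):
    fick = 1.0 * (ca - cb)
    for dv in (1e-3, 1e-4, 1e-6):
        g = electrodiffusive_flux(1, 1.0, ca, cb, dv)
        if fick != 0.0:
            assert abs(g - fick) / abs(fick) < 1e-6 * max(1.0, dv / 1e-6)
    g0 = electrodiffusive_flux(1, 1.0, ca, cb, 1e-9)
    if fick != 0.0:
        assert abs(g0 - fick) / abs(fick) < 1e-8


@pytest.mark.parametrize("zeta", [-5, -2, -0.5, 0.5, 2, 5])
def test_ghk_equal_concentrations_reduce_to_h_zeta_c(zeta):
    # at C_a = C_b = C the GHK bracket collapses to C, so J = h * zeta * C
    dv = zeta / CONSTANTS.F_RT  # z = +1
    c = 42.0
    g = electrodiffusive_flux(1, 2.5, c, c, dv)
    assert g == pytest.approx(2.5 * zeta * c, rel=1e-10)


# -- convection -------------------------------------------------------------


def test_convective_flux_limits_and_value():
    assert convective_flux(1.0, 100.0, 2.0) == 0.0
    assert convective_flux(0.5, 100.0, 0.0) == 0.0
    assert convective_flux(0.3, 100.0, 2.0) == pytest.approx(140.0)


# -- coupled transport ------------------------------------------------------


def test_nkcc2_stoichiometry_is_strict():
    t = TransporterSpec("NKCC2", "cotransporter",
                        {S.NA: 1, S.K: 1, S.CL: 2}, 1.0)
    ca = np.full(15, 10.0)
    cb = np.full(15, 1.0)
    J = coupled_flux(t, ca, cb, 0.0)
    assert J[S.K] == pytest.approx(J[S.NA], rel=1e-12)
    assert J[S.CL] == pytest.approx(2.0 * J[S.NA], rel=1e-12)


def test_coupled_flux_zero_at_equilibrium_for_random_stoichiometries():
    rng = np.random.default_rng(11)
    zf = CONSTANTS.F_RT
    from nephroflux.solutes import VALENCE

    for _ in range(1000):
        solutes = rng.choice(15, size=rng.integers(2, 4), replace=False)
        stoich = {int(k): int(rng.integers(-3, 4)) or 1 for k in solutes}
        cb = np.abs(rng.lognormal(1.0, 0.8, 15)) + 0.1
        dv = float(rng.uniform(-80, 80))
        # choose ln(ca/cb) so the stoichiometry-weighted electrochemical
        # gradient sum(nu * (ln(ca/cb) + z F dV/RT)) vanishes exactly
        nu = np.array([stoich[int(k)] for k in solutes], dtype=float)
        z = np.array([VALENCE[int(k)] for k in solutes], dtype=float)
        y = rng.normal(0.0, 1.0, len(solutes))
        c = float(nu @ (y + z * zf * dv))
        x = y - nu * c / float(nu @ nu)
        ca = cb.copy()
        for k, xi in zip(solutes, x):
            ca[int(k)] = cb[int(k)] * np.exp(xi)
        t = TransporterSpec("rand", "cotransporter", stoich, 1.0)
        J = coupled_flux(t, ca, cb, dv)
        assert np.max(np.abs(J)) < 1e-12


def test_coupled_linear_form_matches_independent_summation():
    rng = np.random.default_rng(3)
    from nephroflux.solutes import VALENCE

    stoich = {S.NA: 1, S.CL: 1}
    t = TransporterSpec("NCC", "cotransporter", stoich, 2.5)
    for _ in range(50):
        ca = np.abs(rng.lognormal(2.0, 0.5, 15)) + 0.1
        cb = np.abs(rng.lognormal(2.0, 0.5, 15)) + 0.1
        dv = float(rng.uniform(-60, 60))
        drive = sum(
            nu * (np.log(ca[k] / cb[k]) + VALENCE[k] * CONSTANTS.F_RT * dv)
            for k, nu in stoich.items()
        )
        J = coupled_flux(t, ca, cb, dv)
        assert J[S.NA] == pytest.approx(2.5 * drive, rel=1e-12)


def test_carrier_kinetics_zero_at_equilibrium_and_bounded():
    t = TransporterSpec(
        "NHE3", "exchanger", {S.NA: 1, S.H: -1}, 1.0,
        km={S.NA: 30.0, S.H: 2.5e-4}, kinetics="carrier",
    )
    ca = np.full(15, 1.0)
    cb = np.full(15, 1.0)
    ca[S.NA], cb[S.NA] = 140.0, 14.0
    ca[S.H], cb[S.H] = 1e-4, 1e-5  # Na_a H_b / (Na_b H_a) = 1 -> equilibrium
    J = coupled_flux(t, ca, cb, 0.0)
    assert abs(J[S.NA]) < 1e-14
    # far from equilibrium the turnover saturates below the activity
    cb[S.H] = 1e-3
    J = coupled_flux(t, ca, cb, 0.0)
    assert 0 < J[S.NA] < 1.0


def test_coupled_flux_rejects_pumps():
    t = TransporterSpec("pump", "ATPase", {S.NA: 3, S.K: -2}, 1.0)
    with pytest.raises(ValueError):
        coupled_flux(t, np.ones(15), np.ones(15), 0.0)


# -- ATPases ----------------------------------------------------------------


def _nak(activity=1.0):
    return TransporterSpec(
        "Na-K-ATPase", "ATPase", {S.NA: 3, S.K: -2}, activity,
        km={S.NA: 12.0, S.K: 1.5}, hill={S.NA: 3.0, S.K: 2.0},
    )


def test_pump_stops_without_substrate():
    ca = np.ones(15)
    ca[S.NA] = 0.0
    J = atpase_flux(_nak(), ca, np.ones(15))
    assert np.all(J == 0.0)


def test_pump_saturates_at_activity():
    ca = np.full(15, 1e6)
    cb = np.full(15, 1e6)
    J = atpase_flux(_nak(), ca, cb)
    assert J[S.NA] == pytest.approx(3.0, rel=1e-4)  # 3 x rate -> activity


def test_pump_flux_ratio_is_three_to_two():
    rng = np.random.default_rng(5)
    for _ in range(20):
        ca = np.abs(rng.lognormal(2, 1, 15)) + 0.01
        cb = np.abs(rng.lognormal(2, 1, 15)) + 0.01
        J = atpase_flux(_nak(), ca, cb)
        assert J[S.NA] == pytest.approx(-1.5 * J[S.K], rel=1e-12)


# -- torque -----------------------------------------------------------------


def _torque(**kw):
    base = dict(r0=1.0, P0=10.0, mu_pt=0.2, l_mv=2.5e-4, delta_mv=1.5e-5,
                s=1.0, tau0=1.0)
    base.update(kw)
    return TorqueParams(**base)


def test_compliant_radius_reference_and_rigid_limits():
    assert compliant_radius(_torque(), 10.0) == pytest.approx(1.0)
    assert compliant_radius(_torque(mu_pt=0.0), 42.0) == pytest.approx(1.0)
    assert compliant_radius(_torque(mu_pt=0.2), 10.5) == pytest.approx(1.1)
    with pytest.raises(ValueError):
        compliant_radius(_torque(mu_pt=0.2), 0.0)


def test_microvillous_torque_formula_and_scalings():
    p = _torque()
    assert microvillous_torque(p, 0.0, 1.0, 7e-3) == 0.0
    t1 = microvillous_torque(p, 1.0, 0.5, 7e-3)
    assert microvillous_torque(p, 2.0, 0.5, 7e-3) == pytest.approx(2 * t1)
    rng = np.random.default_rng(9)
    for _ in range(20):
        Q, r, mu = rng.uniform(0.1, 2), rng.uniform(0.1, 2), rng.uniform(1e-3, 1e-2)
        l, d = rng.uniform(1e-4, 5e-4), rng.uniform(1e-5, 5e-5)
        pp = _torque(l_mv=l, delta_mv=d)
        expected = (8 * mu * Q * l / r**2) * (1 + (l + d) / r + l**2 / (2 * r**2))
        assert microvillous_torque(pp, Q, r, mu) == pytest.approx(expected, rel=1e-12)
    # strictly decreasing in radius at fixed flow
    assert microvillous_torque(p, 1.0, 0.4, 7e-3) > microvillous_torque(p, 1.0, 0.6, 7e-3)


def test_torque_scale_reference_and_gain():
    p = _torque(s=0.7)
    assert torque_scale(p, 1.0) == pytest.approx(1.0)
    assert torque_scale(p, 2.0) == pytest.approx(1.7)
    assert torque_scale(_torque(s=0.0), 5.0) == pytest.approx(1.0)
    assert torque_scale(_torque(s=2.0, floor=0.0), 0.0) == 0.0
    with pytest.raises(ValueError):
        torque_scale(_torque(tau0=0.0), 1.0)


# -- total flux -------------------------------------------------------------


def test_total_flux_is_sum_of_mechanisms(plasma_like):
    rng = np.random.default_rng(13)
    perm = {S.NA: 1e-5, S.K: 2e-5, S.CL: 1e-5, S.UREA: 1e-6}
    m = _membrane(area=0.5, Lp=1e-7, sigma=0.7, perm=perm)
    m.transporters.append(
        TransporterSpec("NCC", "cotransporter", {S.NA: 1, S.CL: 1}, 1e-5)
    )
    m.transporters.append(_nak(1e-5))
    ca = plasma_like * rng.uniform(0.5, 1.5, 15)
    cb = plasma_like * rng.uniform(0.5, 1.5, 15)
    out = total_solute_flux(m, ca, cb, -35.0, 2e-6)
    total = (out["convective"] + out["electrodiffusive"]
             + out["coupled"] + out["ATP-driven"])
    np.testing.assert_allclose(out["total"], total, rtol=1e-12)
    # a membrane with only passive permeability and an uncharged solute
    m2 = _membrane(area=1.0, Lp=0.0, sigma=1.0, perm={S.UREA: 1e-5})
    out2 = total_solute_flux(m2, ca, cb, -35.0, 0.0)
    assert out2["total"][S.UREA] == pytest.approx(
        out2["electrodiffusive"][S.UREA]
    )
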
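"""Coalescence fractions, luminal derivatives and segment marching."""

import numpy as np
import pytest

from nephroflux.constants import DYN_PER_MMHG
from nephroflux.network import (
    InterstitialProfile,
    SegmentGeometry,
    lumen_rhs,
    omega_cnt,
    omega_imcd,
    solve_segment,
)
from nephroflux.parameters import build_toy_fixture, compile_segment
from nephroflux.solutes import GROUP_MATRIX, N_GROUPS


# -- coalescence ------------------------------------------------------------


def test_omega_cnt_endpoints_and_clamp():
    L = 0.2
    assert omega_cnt(0.0, L) == pytest.approx(1.0)
    assert omega_cnt(L / 2, L, clamp=False) == pytest.approx(
        2.0 - np.sqrt(2.32), rel=1e-12
    )
    assert omega_cnt(L, L, clamp=False) == pytest.approx(-0.32, rel=1e-12)
    assert omega_cnt(L, L) == pytest.approx(0.182)


def test_omega_cnt_strictly_decreasing_before_clamp():
    L = 1.0
    xs = np.linspace(0, L, 50)
    vals = [omega_cnt(x, L, clamp=False) for x in xs]
    assert np.all(np.diff(vals) < 0)


def test_omega_imcd_values_and_monotonicity():
    L = 0.5
    assert omega_imcd(0.0, L) == pytest.approx(0.1)
    assert omega_imcd(L / 2, L) == pytest.approx(
        0.1 * (1 - 0.95 * 0.25) * np.exp(-1.375), rel=1e-12
    )
    assert omega_imcd(L / 2, L) == pytest.approx(0.01928, rel=1e-3)
    assert omega_imcd(L, L) == pytest.approx(0.1 * 0.05 * np.exp(-2.75), rel=1e-12)
    assert omega_imcd(L, L) == pytest.approx(3.195e-4, rel=1e-3)
    xs = np.linspace(0, L, 50)
    vals = [omega_imcd(x, L) for x in xs]
    assert np.all(np.diff(vals) < 0)


@pytest.mark.parametrize("fn", [omega_cnt, omega_imcd])
def test_omega_domain_errors(fn):
    with pytest.raises(ValueError):
        fn(-0.1, 1.0)
    with pytest.raises(ValueError):
        fn(1.1, 1.0)


# -- luminal derivatives ----------------------------------------------------


def test_lumen_rhs_poiseuille_matches_hand_evaluation():
    geom = SegmentGeometry("PCT", 1.0, 1e-3, n_grid=4)
    mu, Q, r = 7e-3, 1.0e-6, 1e-3
    _, _, dp = lumen_rhs(Q, 0.0, np.zeros(N_GROUPS), geom, 1.0, r, mu)
    assert dp == pytest.approx(
        -8.0 * mu * Q / (np.pi * r**4) / DYN_PER_MMHG, rel=1e-12
    )


def test_lumen_rhs_zero_flux_conserves_everything():
    geom = SegmentGeometry("SDL", 1.0, 1e-3, n_grid=4)
    dyv, dyg, dp = lumen_rhs(1e-6, 0.0, np.zeros(N_GROUPS), geom, 1.0, 1e-3, 7e-3)
    assert dyv == 0.0
    assert np.all(dyg == 0.0)
    assert dp < 0.0  # pressure still declines under Poiseuille flow


def test_lumen_rhs_coalescing_scales_transport_with_omega():
    geom = SegmentGeometry("CNT", 0.2, 1e-3, n_grid=4, coalescing="CNT")
    jk = np.full(N_GROUPS, 2.0)
    dyv1, dyg1, _ = lumen_rhs(1e-6, 1.0, jk, geom, 1.0, 1e-3, 7e-3)
    dyv2, dyg2, _ = lumen_rhs(1e-6, 1.0, jk, geom, 0.5, 1e-3, 7e-3)
    assert dyv2 == pytest.approx(0.5 * dyv1)
    np.testing.assert_allclose(dyg2, 0.5 * dyg1)


# -- interstitial profile ---------------------------------------------------


def test_interstitial_profile_cortex_matches_plasma_and_rises_with_depth():
    toy = build_toy_fixture()
    prof = toy.interstitial_profile()
    cortex = prof(0.0)
    plasma = toy.plasma_species()
    assert cortex.conc[0] == pytest.approx(plasma[0], rel=0.02)  # Na
    deep = prof(toy.interstitium["om_depth"] + toy.interstitium["im_depth"])
    assert deep.conc.sum() > 1.5 * cortex.conc.sum()
    assert np.all(cortex.conc > 0) and np.all(deep.conc > 0)


# -- segment marching -------------------------------------------------------


def test_zero_length_segment_is_identity():
    toy = build_toy_fixture()
    geom, spec = compile_segment(toy, "mTAL")
    geom.length = 0.0
    prof = toy.interstitial_profile()
    plasma = toy.plasma_species()
    yg = (GROUP_MATRIX @ plasma) * 1e-8
    res = solve_segment(geom, spec, 1e-8, yg, 10.0, prof)
    assert res.yv[-1] == res.yv[0]
    np.testing.assert_array_equal(res.yg[-1], res.yg[0])
    assert res.net_volume_reabsorption == 0.0


def test_segment_march_mass_balance_is_exact():
    toy = build_toy_fixture()
    geom, spec = compile_segment(toy, "PCT")
    prof = toy.interstitial_profile()
    plasma = toy.plasma_species()
    cls = toy.nephron_classes()[0]
    yg = (GROUP_MATRIX @ plasma) * cls.sngfr
    from nephroflux.parameters import _torque_params

    torque = _torque_params(toy, geom.radius, cls.sngfr)
    res = solve_segment(
        geom, spec, cls.sngfr, yg, toy.inlet_pressure, prof,
        torque=torque, viscosity=toy.viscosity, options=toy.solver_options,
    )
    # inlet load minus outlet load equals reported net reabsorption
    np.testing.assert_allclose(
        res.yg[0] - res.yg[-1], res.net_reabsorption, rtol=0, atol=0
    )
    assert res.net_volume_reabsorption == res.yv[0] - res.yv[-1]
    # water is reabsorbed and pressure declines monotonically
    assert res.net_volume_reabsorption > 0
    assert np.all(np.diff(res.P) < 0)
    # luminal fluid stays positive and electroneutral-speciated
    assert np.all(res.conc > 0)


def test_water_abstraction_concentrates_impermeant_solute():
    # descending-limb-like segment: water leaves, urea stays -> [urea] rises
    toy = build_toy_fixture()
    geom, spec = compile_segment(toy, "LDL")
    prof = toy.interstitial_profile()
    plasma = toy.plasma_species()
    yg = (GROUP_MATRIX @ plasma) * 1e-8
    res = solve_segment(geom, spec, 1e-8, yg, 8.0, prof,
                        viscosity=toy.viscosity, options=toy.solver_options)
    assert res.yv[-1] < res.yv[0]
    from nephroflux import solutes as S

    assert res.conc[-1][S.NA] > res.conc[0][S.NA]
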
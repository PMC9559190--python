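"""Protocol surface: deliveries, saline load, swaps, excretion arithmetic."""

import numpy as np
import pytest

from nephroflux.experiments import (
    SWAP_GROUPS,
    delivery_table,
    excretion_ratio,
    fractional_delivery,
    rat_like_activity_deltas,
    run_saline_load,
    sex_swap_model,
)
from nephroflux.network import assemble_kidney
from nephroflux.parameters import apply_deltas, build_model, build_toy_fixture


def test_fractional_delivery_basics():
    assert fractional_delivery(5.0, 5.0) == 100.0
    assert fractional_delivery(0.27, 1.0) == pytest.approx(27.0)
    with pytest.raises(ValueError):
        fractional_delivery(1.0, 0.0)
    # FD(late PT) = 27% means the proximal tubule reabsorbed 73%
    assert 100.0 - fractional_delivery(0.27, 1.0) == pytest.approx(73.0)


def test_excretion_ratio_printed_arithmetic():
    assert excretion_ratio(47.0, 54.0, "rat") == pytest.approx(1.74, abs=0.005)
    assert excretion_ratio(10.0, 11.0, "mouse") == pytest.approx(1.18, abs=0.005)
    assert excretion_ratio(3.0, 3.0, "rat") == pytest.approx(2.0)  # /0.5
    with pytest.raises(ValueError):
        excretion_ratio(-1.0, 2.0)


def test_baseline_pt_inlet_delivery_is_exactly_hundred_percent(toy_baselines):
    table = toy_baselines[("rat", "male")]
    row = table.fractional.loc["PT"]
    for col in table.fractional.columns:
        assert row[col] == pytest.approx(100.0, abs=1e-9)


def test_fractional_deliveries_decline_for_reabsorbed_solutes(toy_baselines):
    frac = toy_baselines[("rat", "male")].fractional
    # volume and Na+ fall monotonically from filtrate to urine at toy scale
    assert frac.loc["urine", "volume"] < frac.loc["DCT", "volume"] \
        < frac.loc["PT", "volume"]
    assert frac.loc["urine", "Na+"] < frac.loc["PT", "Na+"]


def test_segment_reabsorptions_plus_excretion_close_the_budget(toy_baselines):
    sol = toy_baselines[("rat", "male")].solution
    segs = ["PCT", "S3", "SDL", "LDL", "LAL", "mTAL", "cTAL", "DCTe", "DCTl",
            "CNT", "CCD", "OMCD", "IMCD"]
    reab = sum(sol.kidney_reabsorption(sg)[0] for sg in segs)
    assert (reab + sol.urine_flow) == pytest.approx(
        sol.filtered_volume, rel=1e-9
    )


@pytest.mark.parametrize("sex,factor", [("male", 1.50), ("female", 1.65)])
def test_saline_load_scales_sngfr_exactly(toy_models, toy_baselines, sex, factor):
    base = toy_baselines[("rat", sex)]
    loaded = run_saline_load(toy_models[("rat", sex)], base)
    assert loaded.solution.filtered_volume == pytest.approx(
        factor * base.solution.filtered_volume, rel=1e-12
    )
    # diuresis: saline-load urine flow exceeds baseline
    assert loaded.solution.urine_flow > base.solution.urine_flow


def test_saline_load_raises_absolute_proximal_sodium_reabsorption(
    toy_models, toy_baselines
):
    from nephroflux.solutes import GROUP_NAMES

    gi = GROUP_NAMES.index("Na")
    for key, base in toy_baselines.items():
        loaded = run_saline_load(toy_models[key], base)
        for sol_pair in [(base.solution, loaded.solution)]:
            b = sum(sol_pair[0].kidney_reabsorption(sg)[1][gi]
                    for sg in ("PCT", "S3"))
            n = sum(sol_pair[1].kidney_reabsorption(sg)[1][gi]
                    for sg in ("PCT", "S3"))
            assert n > b  # glomerulotubular balance


def test_identical_models_solve_to_identical_outputs(toy_models):
    # an empty swap (no deltas) is an exact no-op: deterministic resolve
    model = toy_models[("mouse", "male")]
    s1 = assemble_kidney(apply_deltas(model, []))
    s2 = assemble_kidney(apply_deltas(model, []))
    assert np.array_equal(s1.urine_species, s2.urine_species)
    assert s1.urine_flow == s2.urine_flow


def test_pt_swap_is_a_pure_nhe3_increase_of_47_percent():
    deltas = rat_like_activity_deltas(SWAP_GROUPS["PT"])
    assert len(deltas) == 1
    d = deltas[0]
    assert d.parameter == "NHE3"
    assert d.change == pytest.approx(0.470588, rel=1e-4)
    assert set(d.segments) == {"PCT", "S3"}


def test_tal_swap_only_restores_the_sodium_pump():
    deltas = rat_like_activity_deltas(SWAP_GROUPS["TAL"])
    assert [d.parameter for d in deltas] == ["NKA"]
    # undoing a 13% reduction is roughly a 15% increase
    assert deltas[0].change == pytest.approx(1 / 0.87 - 1, rel=1e-9)


def test_cnt_swap_restores_apical_pk_and_hka():
    params = {d.parameter for d in rat_like_activity_deltas(SWAP_GROUPS["CNT"])}
    assert params == {"apical_PK", "HKA"}


def test_sex_swap_pt_pf_sets_female_water_permeability_rat_like():
    male = build_model("mouse", "male")
    swapped = sex_swap_model("PT_Pf")
    for seg in ("PCT", "S3"):
        lp_m = male.segments[seg]["cells"]["main"]["apical"]["Lp"]
        lp_s = swapped.segments[seg]["cells"]["main"]["apical"]["Lp"]
        assert lp_s == pytest.approx(0.64 * lp_m, rel=1e-12)


def test_sex_swap_tal_nka_doubles_male_pump_activity():
    male = build_model("mouse", "male")
    swapped = sex_swap_model("TAL_NKA")
    for seg in ("mTAL", "cTAL", "DCTe", "DCTl", "CNT"):
        for cname, cell in swapped.segments[seg]["cells"].items():
            for t_s, t_m in zip(
                cell["basolateral"]["transporters"],
                male.segments[seg]["cells"][cname]["basolateral"]["transporters"],
            ):
                if t_s["name"] == "Na-K-ATPase":
                    assert t_s["activity"] == pytest.approx(
                        2.0 * t_m["activity"], rel=1e-12
                    )


def test_sex_swap_enac_steps_are_30_50_20_percent_above_male():
    male = build_model("mouse", "male")
    swapped = sex_swap_model("ENaC")
    factors = {"CNT": 1.30, "CCD": 1.50, "OMCD": 1.20}
    for seg, f in factors.items():
        for cname, cell in swapped.segments[seg]["cells"].items():
            for t_s, t_m in zip(
                cell["apical"]["transporters"],
                male.segments[seg]["cells"][cname]["apical"]["transporters"],
            ):
                if t_s["name"] == "ENaC":
                    assert t_s["activity"] == pytest.approx(
                        f * t_m["activity"], rel=1e-12
                    )
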
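"""The four in-silico protocols and delivery/excretion accounting.

Protocols:

* ``baseline`` — solve a sex/species model and tabulate absolute and
  fractional deliveries of volume and key solutes to each segment inlet.
* ``saline_load`` — re-solve with SNGFR raised 50% (males) or 65%
  (females), other parameters unchanged, and report flows and excretions.
* ``segment_swap`` — set the transporter and channel activities of one
  mouse segment group to the sex-matched rat values (by inverting the
  rat-to-mouse activity deltas for that group) and report the fractional
  changes in segmental transport and excretion.
* ``sex_swap`` — make one of three sex differences in the female mouse
  rat-like (proximal water permeability, distal Na-K-ATPase, ENaC) and
  report the fractional changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import KidneySolution, assemble_kidney
from .parameters import (
    ModelParameterSet,
    ParameterDelta,
    apply_deltas,
    build_model,
    invert_delta,
    load_deltas,
)
from .solutes import GROUP_NAMES
from . import solutes as sol

_GI = {g: i for i, g in enumerate(GROUP_NAMES)}

#: segment-inlet boundaries reported in delivery tables, in flow order
BOUNDARIES = ("PT", "DL", "mTAL", "DCT", "CNT", "CCD", "urine")
_BOUNDARY_SEGMENT = {
    "PT": "PCT", "DL": "SDL", "mTAL": "mTAL", "DCT": "DCTe", "CNT": "CNT",
}
#: species columns of the delivery tables
TABLE_SPECIES = ("volume", "Na+", "K+", "Cl-", "HCO3-", "NH4+")
_SPECIES_INDEX = {"Na+": sol.NA, "K+": sol.K, "Cl-": sol.CL,
                  "HCO3-": sol.HCO3, "NH4+": sol.NH4}

#: saline-load SNGFR factors (greater in females, reflecting their larger
#: salt-loading-induced NOS1beta response)
SALINE_SNGFR_FACTOR = {"male": 1.50, "female": 1.65}

#: segment groups for the segment-swap protocol
SWAP_GROUPS = {
    "PT": ("PCT", "S3"),
    "TAL": ("mTAL", "cTAL"),
    "DCT": ("DCTe", "DCTl"),
    "CNT": ("CNT",),
    "CCD_OMCD": ("CCD", "OMCD"),
    "IMCD": ("IMCD",),
}

#: parameters counted as "transporter and channel activities" when a mouse
#: segment is made rat-like (geometry and SNGFR are explicitly excluded)
_ACTIVITY_PARAMS = {
    "NHE3", "NHE", "SGLT2", "NaPi", "NKCC2", "NKCC", "NCC", "KCC4", "KCC",
    "ENaC", "NKA", "HKA", "apical_PK", "apical_PNa", "apical_PCl",
    "para_PNa", "para_PK", "para_PCl",
}

SEX_SWAP_FEATURES = ("PT_Pf", "TAL_NKA", "ENaC")


@dataclass
class DeliveryTable:
    """Delivery of volume and key solutes to segment inlets, per kidney.

    ``absolute`` rows are uL/min (volume) and umol/min (solutes);
    ``fractional`` rows are percent of the filtered load.  The last row
    is the urinary excretion.
    """

    absolute: pd.DataFrame
    fractional: pd.DataFrame
    solution: KidneySolution

    @property
    def urine(self) -> pd.Series:
        return self.absolute.loc["urine"]

    def fractional_excretion(self, species: str) -> float:
        """Urinary excretion as percent of the filtered load."""
        return float(self.fractional.loc["urine", species])

    def to_text(self) -> str:
        out = ["# absolute deliveries (volume uL/min, solutes umol/min)"]
        out.append(self.absolute.to_csv(sep="\t", float_format="%.6g"))
        out.append("# fractional deliveries (% of filtered load)")
        out.append(self.fractional.to_csv(sep="\t", float_format="%.6g"))
        return "\n".join(out)


def fractional_delivery(delivery: float, filtered_load: float) -> float:
    """Delivery at a boundary as a percentage of the filtered load."""
    if filtered_load <= 0:
        raise ValueError("filtered load must be positive")
    return 100.0 * delivery / filtered_load


def _boundary_deliveries(solution: KidneySolution) -> dict[str, np.ndarray]:
    """Per-kidney volume+species delivery vector at each boundary."""
    out = {}
    for b in BOUNDARIES:
        if b == "urine":
            vol = solution.urine_flow
            spc = solution.urine_species
        elif b == "CCD":
            vol = solution.collecting_duct[0].yv[0] * solution.nephron_count
            spc = (
                solution.collecting_duct[0].species_delivery(0)
                * solution.nephron_count
            )
        else:
            seg = _BOUNDARY_SEGMENT[b]
            vol = 0.0
            spc = np.zeros(15)
            for label, results in solution.classes.items():
                w = solution.class_weights[label] * solution.nephron_count
                for r in results:
                    if r.geometry.id == seg:
                        vol += w * r.yv[0]
                        spc += w * r.species_delivery(0)
        out[b] = np.concatenate([[vol], spc])
    return out


def delivery_table(solution: KidneySolution) -> DeliveryTable:
    """Assemble the delivery table from a solved kidney."""
    bounds = _boundary_deliveries(solution)
    filt = np.concatenate([[solution.filtered_volume], solution.filtered_species])
    rows_abs, rows_frac = [], []
    for b in BOUNDARIES:
        vec = bounds[b]
        row_abs, row_frac = {}, {}
        for name in TABLE_SPECIES:
            if name == "volume":
                v, f = vec[0], filt[0]
                row_abs[name] = v * 60.0e3  # cm^3/s -> uL/min
            else:
                k = _SPECIES_INDEX[name]
                v, f = vec[1 + k], filt[1 + k]
                row_abs[name] = v * 60.0  # umol/s -> umol/min
            row_frac[name] = fractional_delivery(v, f)
        rows_abs.append(row_abs)
        rows_frac.append(row_frac)
    index = list(BOUNDARIES)
    return DeliveryTable(
        absolute=pd.DataFrame(rows_abs, index=index),
        fractional=pd.DataFrame(rows_frac, index=index),
        solution=solution,
    )


# ---------------------------------------------------------------------------
# protocols
# ---------------------------------------------------------------------------


def run_baseline(
    model: ModelParameterSet, warm: dict | None = None
) -> DeliveryTable:
    """Solve a model at baseline and tabulate deliveries."""
    solution = assemble_kidney(model, warm=warm)
    return delivery_table(solution)


def run_saline_load(
    model: ModelParameterSet,
    baseline: DeliveryTable | None = None,
) -> DeliveryTable:
    """Acute saline load: SNGFR x1.50 (male) or x1.65 (female).

    All other parameters remain unchanged; the torque reference stays at
    its baseline value, so flow-activated proximal transport (a form of
    glomerulotubular balance) responds to the extra load.
    """
    factor = SALINE_SNGFR_FACTOR[model.sex]
    warm = baseline.solution.warm_starts() if baseline is not None else None
    solution = assemble_kidney(model, sngfr_scale=factor, warm=warm)
    return delivery_table(solution)


def excretion_ratio(
    e_female: float, e_male: float, species: str = "rat"
) -> float:
    """Female-to-male excretion ratio normalised by saline bolus volume.

    The bolus scales with body weight: a female rat weighs about half a
    male (divide the excretion ratio by 0.5); a male mouse weighs about
    30% more than a female (multiply by 1.3).
    """
    if e_female <= 0 or e_male <= 0:
        raise ValueError("excretion rates must be positive")
    if species == "rat":
        return (e_female / e_male) / 0.5
    if species == "mouse":
        return (e_female / e_male) * 1.3
    raise ValueError("species must be 'rat' or 'mouse'")


def rat_like_activity_deltas(group: tuple[str, ...]) -> list[ParameterDelta]:
    """Inverted rat-to-mouse activity deltas restricted to a segment group."""
    deltas, _ = load_deltas("deltas_mouse_m")
    out = []
    for d in deltas:
        if d.change is None or d.segments is None:
            continue
        if d.parameter not in _ACTIVITY_PARAMS:
            continue  # geometry and SNGFR stay mouse
        segs = tuple(s for s in d.segments if s in group)
        if not segs:
            continue
        out.append(ParameterDelta(d.parameter, invert_delta(d.change), segs))
    return out


@dataclass
class SwapReport:
    """Fractional changes produced by a swap experiment."""

    #: per-segment-group fractional change in net transport (Na+, K+, volume)
    segment_changes: dict[str, dict[str, float]]
    #: fractional changes in urinary Na+, K+ excretion and urine output
    excretion_changes: dict[str, float]
    baseline: DeliveryTable
    perturbed: DeliveryTable


def _transport_changes(
    base: KidneySolution, new: KidneySolution, segments: tuple[str, ...]
) -> dict[str, float]:
    def net(solution, what):
        vol = 0.0
        grp = np.zeros(len(GROUP_NAMES))
        for seg in segments:
            v, g = solution.kidney_reabsorption(seg)
            vol += v
            grp += g
        if what == "volume":
            return vol
        return grp[_GI[what]]

    out = {}
    for label, key in (("Na+", "Na"), ("K+", "K"), ("volume", "volume")):
        b = net(base, key)
        n = net(new, key)
        out[label] = (n - b) / abs(b) if b != 0 else np.nan
    return out


def _excretion_changes(base: DeliveryTable, new: DeliveryTable) -> dict[str, float]:
    out = {}
    for label, col in (("Na+ excretion", "Na+"), ("K+ excretion", "K+"),
                       ("urine output", "volume")):
        b = base.absolute.loc["urine", col]
        n = new.absolute.loc["urine", col]
        out[label] = (n - b) / b
    return out


def run_segment_swap(
    sex: str,
    group: str,
    baseline: DeliveryTable | None = None,
    model: ModelParameterSet | None = None,
) -> SwapReport:
    """Give one mouse segment group the sex-matched rat activities.

    Only transporter and channel activities change (for the proximal
    tubule that is a 47% NHE3 increase, undoing the 32% rat-to-mouse
    reduction); SNGFR and segment dimensions stay mouse.  ``model`` may
    supply a prebuilt (e.g. toy-fidelity) mouse parameter set.
    """
    if group not in SWAP_GROUPS:
        raise ValueError(f"unknown segment group {group!r}")
    if model is None:
        model = build_model("mouse", sex)
    if baseline is None:
        baseline = run_baseline(model)
    swapped = apply_deltas(model, rat_like_activity_deltas(SWAP_GROUPS[group]))
    new = delivery_table(
        assemble_kidney(swapped, warm=baseline.solution.warm_starts())
    )
    return SwapReport(
        segment_changes={
            group: _transport_changes(
                baseline.solution, new.solution, SWAP_GROUPS[group]
            )
        },
        excretion_changes=_excretion_changes(baseline, new),
        baseline=baseline,
        perturbed=new,
    )


def sex_swap_model(
    feature: str,
    male: ModelParameterSet | None = None,
    female: ModelParameterSet | None = None,
) -> ModelParameterSet:
    """Female-mouse set with one sex difference made rat-like."""
    male = male if male is not None else build_model("mouse", "male")
    female = (female if female is not None else build_model("mouse", "female")).copy()
    if feature == "PT_Pf":
        # proximal apical water permeability set 36% below the male value
        # (rat-like), instead of 40% above it
        for seg in ("PCT", "S3"):
            for cname, cell in female.segments[seg]["cells"].items():
                male_lp = male.segments[seg]["cells"][cname]["apical"]["Lp"]
                cell["apical"]["Lp"] = 0.64 * male_lp
        return female
    if feature == "TAL_NKA":
        # Na-K-ATPase along TAL, DCT and CNT doubled from the male value
        for seg in ("mTAL", "cTAL", "DCTe", "DCTl", "CNT"):
            for cname, cell in female.segments[seg]["cells"].items():
                for t_f, t_m in zip(
                    cell["basolateral"]["transporters"],
                    male.segments[seg]["cells"][cname]["basolateral"]["transporters"],
                ):
                    if t_f["name"] == "Na-K-ATPase":
                        t_f["activity"] = 2.0 * t_m["activity"]
        return female
    if feature == "ENaC":
        # ENaC 30% / 50% / 20% above male along CNT / CCD / OMCD (rat-like)
        factors = {"CNT": 1.30, "CCD": 1.50, "OMCD": 1.20}
        for seg, f in factors.items():
            for cname, cell in female.segments[seg]["cells"].items():
                for t_f, t_m in zip(
                    cell["apical"]["transporters"],
                    male.segments[seg]["cells"][cname]["apical"]["transporters"],
                ):
                    if t_f["name"] == "ENaC":
                        t_f["activity"] = f * t_m["activity"]
        return female
    raise ValueError(f"unknown sex-swap feature {feature!r}")


_FEATURE_SEGMENTS = {
    "PT_Pf": ("PCT", "S3"),
    "TAL_NKA": ("mTAL", "cTAL", "DCTe", "DCTl", "CNT"),
    "ENaC": ("CNT", "CCD", "OMCD"),
}


def run_sex_swap(
    feature: str,
    baseline: DeliveryTable | None = None,
    male: ModelParameterSet | None = None,
    female: ModelParameterSet | None = None,
) -> SwapReport:
    """Make one female-mouse sex difference rat-like; see module docstring."""
    if feature not in SEX_SWAP_FEATURES:
        raise ValueError(f"unknown sex-swap feature {feature!r}")
    if baseline is None:
        baseline = run_baseline(
            female if female is not None else build_model("mouse", "female")
        )
    model = sex_swap_model(feature, male=male, female=female)
    new = delivery_table(
        assemble_kidney(model, warm=baseline.solution.warm_starts())
    )
    segs = _FEATURE_SEGMENTS[feature]
    return SwapReport(
        segment_changes={
            feature: _transport_changes(baseline.solution, new.solution, segs)
        },
        excretion_changes=_excretion_changes(baseline, new),
        baseline=baseline,
        perturbed=new,
    )
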
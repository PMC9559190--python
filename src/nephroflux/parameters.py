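"""Parameter sets, the species/sex delta engine, and the toy fixture.

The packaged base set is a best-effort transcription of a male-rat nephron
model (absolute permeabilities, transporter activities and geometry).  The
female-rat, male-mouse and female-mouse sets are derived from it by
applying layered relative-change files (the delta engine): each delta row
names a segment group, a parameter, and a signed fractional change;
``value_new = value_old * (1 + change)``.  Length and diameter changes
rescale tubule length, radius and membrane areas (transport area is
proportional to length times diameter).

Every value carries a provenance tag: ``transcribed`` (base set),
``delta-derived`` (touched by a delta chain) or ``fixture`` (toy set).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .epithelium import CellSpec, EpitheliumSpec, SolverOptions
from .fluxes import MembraneSpec, TorqueParams, TransporterSpec, microvillous_torque
from .network import InterstitialProfile, NephronClass, SegmentGeometry
from .solutes import (
    CL,
    GLU,
    GROUP_NAMES,
    H,
    HCO2,
    HCO3,
    HPO4,
    K,
    NA,
    NH4,
    N_SOLUTES,
    VALENCE,
    solute_index,
    speciate,
)

# ---------------------------------------------------------------------------
# transporter catalogue
# ---------------------------------------------------------------------------

#: Kinetic skeletons for the named transporters of the model family.
#: Apical entries are oriented lumen->cell, basolateral entries cell->bath
#: (or cell->interspace); activities come from the parameter files.
TRANSPORTER_CATALOG: dict[str, dict] = {
    "NHE3": dict(
        kind="exchanger",
        stoich={NA: 1, H: -1},
        modes=((0.85, {NA: 1, H: -1}), (0.15, {NA: 1, NH4: -1})),
        km={NA: 30.0, H: 2.5e-4, NH4: 10.0},
        kinetics="carrier",
    ),
    "NHE": dict(
        kind="exchanger",
        stoich={NA: 1, H: -1},
        modes=((0.9, {NA: 1, H: -1}), (0.1, {NA: 1, NH4: -1})),
        km={NA: 30.0},
    ),
    "SGLT2": dict(kind="cotransporter", stoich={NA: 1, GLU: 1}, km={GLU: 2.0}),
    "NaPi": dict(kind="cotransporter", stoich={NA: 2, HPO4: 1}, km={HPO4: 0.8}),
    "NKCC2": dict(
        kind="cotransporter",
        stoich={NA: 1, K: 1, CL: 2},
        modes=((0.8, {NA: 1, K: 1, CL: 2}), (0.2, {NA: 1, NH4: 1, CL: 2})),
    ),
    "NKCC": dict(kind="cotransporter", stoich={NA: 1, K: 1, CL: 2}),
    "NCC": dict(kind="cotransporter", stoich={NA: 1, CL: 1}),
    "KCC4": dict(kind="cotransporter", stoich={K: 1, CL: 1}),
    "KCC": dict(kind="cotransporter", stoich={K: 1, CL: 1}),
    "NHE1": dict(
        kind="exchanger",
        stoich={NA: -1, H: 1},  # basolateral: Na+ in, H+ out of the cell
        km={},
    ),
    "NBC": dict(kind="cotransporter", stoich={NA: 1, HCO3: 3}),
    "AE": dict(kind="exchanger", stoich={CL: -1, HCO3: 1}),
    "CFEX": dict(kind="exchanger", stoich={CL: 1, HCO2: -1}),
    "ENaC": dict(kind="channel", stoich={NA: 1}),
    "Na-K-ATPase": dict(
        kind="ATPase",
        stoich={NA: 3, K: -2},
        km={NA: 12.0, K: 1.5},
        hill={NA: 3.0, K: 2.0},
        km_modulation=(K, 8.33),
    ),
    "H-K-ATPase": dict(kind="ATPase", stoich={H: -1, K: 1}, km={K: 1.0}),
}

_ACTIVITY_ALIASES = {"NKA": "Na-K-ATPase", "HKA": "H-K-ATPase"}

#: default gas/acid permeabilities on cell membranes (cm/s)
_CELL_MEMBRANE_DEFAULTS = {
    "CO2": 2.0e-3, "NH3": 8.0e-4, "H2CO3": 8.0e-4, "H": 1.0e-4,
    # small anion leak: keeps the phosphate pool kinetically anchored and
    # lets NaPi-transported phosphate exit the cell
    "HPO4": 2.0e-7, "H2PO4": 2.0e-7,
}
_TJ_DEFAULTS = {"CO2": 1.0e-3, "NH3": 1.0e-4, "H2CO3": 1.0e-4}

#: tubule segment order per nephron class
SF_SEGMENTS = ("PCT", "S3", "SDL", "mTAL", "cTAL", "DCTe", "DCTl", "CNT")
JM_SEGMENTS = ("PCT", "S3", "SDL", "LDL", "LAL", "mTAL", "cTAL", "DCTe", "DCTl", "CNT")
CD_SEGMENTS = ("CCD", "OMCD", "IMCD")


def make_transporter(name: str, activity: float, **overrides) -> TransporterSpec:
    """Instantiate a catalogue transporter with a given activity."""
    if name not in TRANSPORTER_CATALOG:
        raise KeyError(f"unknown transporter {name!r}")
    info = {**TRANSPORTER_CATALOG[name], **overrides}
    return TransporterSpec(
        name=name,
        kind=info["kind"],
        stoich=dict(info["stoich"]),
        activity=activity,
        km=dict(info.get("km", {})),
        modes=tuple(info.get("modes", ())),
        hill=dict(info.get("hill", {})),
        km_modulation=info.get("km_modulation"),
        kinetics=info.get("kinetics", "linear"),
    )


# ---------------------------------------------------------------------------
# parameter set
# ---------------------------------------------------------------------------


@dataclass
class ParameterDelta:
    """One relative parameter change from the species/sex difference table."""

    parameter: str
    change: float | None  # None encodes a printed "no change" entry
    segments: tuple[str, ...] | None = None
    note: str = ""

    def __post_init__(self) -> None:
        if self.change is not None and self.change <= -1.0:
            raise ValueError("relative change must be > -1")


def invert_delta(change: float) -> float:
    """The restoring change: applying ``change`` then the result is identity.

    E.g. a -32% reduction is undone by a +47.06% increase.
    """
    if change <= -1.0:
        raise ValueError("relative change must be > -1")
    return 1.0 / (1.0 + change) - 1.0


@dataclass
class ModelParameterSet:
    """A fully resolved species/sex parameter set."""

    species: str
    sex: str
    nephron_count: float
    sngfr_sf: float  # cm^3/s
    jm_sngfr_ratio: float
    class_weights: dict[str, float]
    loop_depths: dict[str, float]
    plasma: dict[str, float]  # group totals (mM) + "pH"
    inlet_pressure: float
    bath_pressure: float
    viscosity: float
    torque: dict[str, float]
    interstitium: dict
    segments: dict[str, dict]
    solver: dict = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    # -- derived views ----------------------------------------------------
    def copy(self) -> "ModelParameterSet":
        return copy.deepcopy(self)

    @property
    def solver_options(self) -> SolverOptions:
        return SolverOptions(**self.solver)

    def plasma_species(self) -> np.ndarray:
        """Electroneutral filtrate composition (15 species, mM).

        The chloride total is adjusted once so the mixture is neutral at
        the prescribed plasma pH; the final speciation then uses the same
        electroneutral, carbonate-equilibrium convention as luminal fluid,
        so fractional deliveries at the proximal inlet are exactly 100%.
        """
        totals = {g: self.plasma[g] for g in GROUP_NAMES}
        conc = speciate(totals, pH=self.plasma.get("pH", 7.4))
        totals["Cl"] = max(totals["Cl"] + float(VALENCE @ conc), 1.0)
        return speciate(totals, carbonate_equilibrium=True)

    def interstitial_profile(self) -> InterstitialProfile:
        cfg = self.interstitium
        return InterstitialProfile(
            plasma_totals={g: self.plasma[g] for g in GROUP_NAMES},
            pH=self.plasma.get("pH", 7.4),
            pressure=self.bath_pressure,
            om_depth=cfg["om_depth"],
            im_depth=cfg["im_depth"],
            om_boundary=cfg.get("om_boundary", {}),
            tip=cfg.get("tip", {}),
        )

    def nephron_classes(self) -> list[NephronClass]:
        out = []
        for label, w in self.class_weights.items():
            if label == "SF":
                out.append(NephronClass(label, w, self.sngfr_sf, 0.0))
            else:
                out.append(
                    NephronClass(
                        label,
                        w,
                        self.sngfr_sf * self.jm_sngfr_ratio,
                        self.loop_depths[label],
                    )
                )
        return out

    def provenance_report(self) -> str:
        """Summary of where each parameter value came from."""
        counts: dict[str, int] = {}
        for tag in self.provenance.values():
            counts[tag] = counts.get(tag, 0) + 1
        lines = [f"# provenance report: {self.species} {self.sex}"]
        for tag, n in sorted(counts.items()):
            lines.append(f"{tag}\t{n}")
        for path, tag in sorted(self.provenance.items()):
            lines.append(f"{path}\t{tag}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------


def _data_text(name: str) -> str:
    return resources.files("nephroflux.data").joinpath(name).read_text()


def load_base(name: str = "rat_male") -> ModelParameterSet:
    """Load a packaged base parameter file."""
    raw = yaml.safe_load(_data_text(f"{name}.yaml"))
    seg = raw["segments"]
    prov = {}

    def walk(prefix, node):
        if isinstance(node, dict):
            for k, v in node.items():
                walk(f"{prefix}.{k}", v)
        elif isinstance(node, list):
            for i, v in enumerate(node):
                walk(f"{prefix}[{i}]", v)
        else:
            prov[prefix] = "transcribed"

    walk("", raw)
    return ModelParameterSet(
        species=raw["species"],
        sex=raw["sex"],
        nephron_count=raw["nephron_count"],
        sngfr_sf=raw["sngfr_sf"],
        jm_sngfr_ratio=raw["jm_sngfr_ratio"],
        class_weights=raw["class_weights"],
        loop_depths=raw["loop_depths"],
        plasma=raw["plasma"],
        inlet_pressure=raw["inlet_pressure"],
        bath_pressure=raw["bath_pressure"],
        viscosity=raw["viscosity"],
        torque=raw["torque"],
        interstitium=raw["interstitium"],
        segments=seg,
        solver=raw.get("solver", {}),
        provenance=prov,
    )


def load_deltas(name: str) -> tuple[list[ParameterDelta], dict]:
    """Load a packaged delta file; returns (deltas, species-level overrides)."""
    raw = yaml.safe_load(_data_text(f"{name}.yaml"))
    deltas = []
    for row in raw["deltas"]:
        deltas.append(
            ParameterDelta(
                parameter=row["parameter"],
                change=row.get("change"),
                segments=tuple(row["segments"]) if row.get("segments") else None,
                note=row.get("note", ""),
            )
        )
    return deltas, raw.get("overrides", {})


# ---------------------------------------------------------------------------
# delta application
# ---------------------------------------------------------------------------

_MEMBRANE_KEYS = ("apical", "basolateral")


class DeltaResolutionError(KeyError):
    """A delta row names a parameter absent from the target segment."""


def _scale_transporter(seg: dict, seg_id: str, name: str, factor: float) -> int:
    hits = 0
    for cell in seg["cells"].values():
        for mk in _MEMBRANE_KEYS:
            mem = cell.get(mk)
            if not mem:
                continue
            for t in mem.get("transporters", []):
                if t["name"] == name:
                    t["activity"] *= factor
                    hits += 1
    return hits


def _apply_one(model: ModelParameterSet, delta: ParameterDelta) -> list[str]:
    """Apply a single delta row in place; returns touched provenance paths."""
    if delta.change is None:
        return []
    f = 1.0 + delta.change
    p = delta.parameter
    touched: list[str] = []

    if p == "sngfr":
        model.sngfr_sf *= f
        return ["sngfr_sf"]
    if p == "plasma_K":
        model.plasma["K"] *= f
        for level in ("om_boundary", "tip"):
            if "K" in model.interstitium.get(level, {}):
                model.interstitium[level]["K"] *= f
        return ["plasma.K"]

    if delta.segments is None:
        raise DeltaResolutionError(f"parameter {p!r} needs a segment list")

    for seg_id in delta.segments:
        if seg_id not in model.segments:
            raise DeltaResolutionError(f"unknown segment {seg_id!r} in delta {p!r}")
        seg = model.segments[seg_id]
        if p == "length":
            seg["length"] *= f
            touched.append(f"segments.{seg_id}.length")
        elif p == "diameter":
            # transport area ~ length x diameter: rescale radius and areas
            seg["radius"] *= f
            for cell in seg["cells"].values():
                for mk in _MEMBRANE_KEYS:
                    if cell.get(mk):
                        cell[mk]["area"] *= f
            for mk in ("tight_junction", "basement"):
                seg[mk]["area"] *= f
            touched.append(f"segments.{seg_id}.radius")
        elif p == "apical_Pf":
            for cname, cell in seg["cells"].items():
                cell["apical"]["Lp"] *= f
                touched.append(f"segments.{seg_id}.cells.{cname}.apical.Lp")
        elif p in ("apical_PNa", "apical_PK", "apical_PCl"):
            k = {"apical_PNa": "Na", "apical_PK": "K", "apical_PCl": "Cl"}[p]
            hit = False
            for cname, cell in seg["cells"].items():
                perm = cell["apical"].setdefault("perm", {})
                if k in perm:
                    perm[k] *= f
                    hit = True
                    touched.append(f"segments.{seg_id}.cells.{cname}.apical.perm.{k}")
            if not hit:
                raise DeltaResolutionError(
                    f"segment {seg_id} has no apical {k} permeability"
                )
        elif p in ("para_PNa", "para_PK", "para_PCl"):
            k = {"para_PNa": "Na", "para_PK": "K", "para_PCl": "Cl"}[p]
            perm = seg["tight_junction"].setdefault("perm", {})
            if k not in perm:
                raise DeltaResolutionError(
                    f"segment {seg_id} has no paracellular {k} permeability"
                )
            perm[k] *= f
            touched.append(f"segments.{seg_id}.tight_junction.perm.{k}")
        else:
            name = _ACTIVITY_ALIASES.get(p, p)
            hits = _scale_transporter(seg, seg_id, name, f)
            if hits == 0:
                raise DeltaResolutionError(
                    f"segment {seg_id} carries no transporter {name!r}"
                )
            touched.append(f"segments.{seg_id}.transporter.{name}")
    return touched


def apply_deltas(
    base: ModelParameterSet, deltas: list[ParameterDelta]
) -> ModelParameterSet:
    """Apply a delta list to a copy of ``base``; untouched values are shared
    bit-identically (deep copy of equal floats)."""
    model = base.copy()
    for d in deltas:
        for path in _apply_one(model, d):
            model.provenance[path] = "delta-derived"
    return model


# ---------------------------------------------------------------------------
# the four models
# ---------------------------------------------------------------------------


def build_model(species: str, sex: str) -> ModelParameterSet:
    """Build one of the four packaged models by its documented delta chain."""
    if species not in ("rat", "mouse") or sex not in ("male", "female"):
        raise ValueError("species in {rat, mouse}, sex in {male, female}")
    base = load_base("rat_male")
    if species == "rat" and sex == "male":
        return base
    if species == "rat":
        deltas, _ = load_deltas("deltas_rat_f")
        model = apply_deltas(base, deltas)
        model.sex = "female"
        return model
    deltas, overrides = load_deltas("deltas_mouse_m")
    model = apply_deltas(base, deltas)
    model.species, model.sex = "mouse", "male"
    for key, val in overrides.items():
        setattr(model, key, val)
        model.provenance[key] = "delta-derived"
    if sex == "male":
        return model
    deltas_f, _ = load_deltas("deltas_mouse_f")
    model = apply_deltas(model, deltas_f)
    model.sex = "female"
    return model


def build_toy_fixture(
    species: str = "rat",
    sex: str = "male",
    length_scale: float = 0.3,
    n_grid: int = 4,
    n_grid_imcd: int = 16,
    classes: tuple[str, ...] = ("SF", "JM1", "JM3"),
) -> ModelParameterSet:
    """A miniature self-consistent parameter set for fast tests.

    Derived from the packaged sets by shortening every tubule segment,
    coarsening the axial grid and keeping a reduced nephron-class set
    (renormalised weights); every code path stays live: compliant proximal
    tubule, coalescing CNT and IMCD, long-loop segments, principal and
    intercalated cells, and all transporter kinds.
    """
    model = build_model(species, sex)
    for seg_id, seg in model.segments.items():
        seg["length"] *= length_scale
        # the coalescing inner-medullary duct needs a finer grid: its
        # population fraction decays exponentially over the segment
        seg["n_grid"] = n_grid_imcd if seg_id == "IMCD" else n_grid
    for label in model.loop_depths:
        model.loop_depths[label] *= length_scale
    model.interstitium["om_depth"] *= length_scale
    model.interstitium["im_depth"] *= length_scale
    for seg in model.segments.values():
        seg["depth"] = [d * length_scale for d in seg["depth"]]
    kept = {k: model.class_weights[k] for k in classes}
    total = sum(kept.values())
    model.class_weights = {k: v / total for k, v in kept.items()}
    model.loop_depths = {
        k: v for k, v in model.loop_depths.items() if k in classes
    }
    for path in list(model.provenance):
        model.provenance[path] = "fixture"
    return model


# ---------------------------------------------------------------------------
# compilation to solver structures
# ---------------------------------------------------------------------------


def _perm_array(d: dict | None, defaults: dict | None = None) -> np.ndarray:
    out = np.zeros(N_SOLUTES)
    if defaults:
        for name, v in defaults.items():
            out[solute_index(name)] = v
    if d:
        for name, v in d.items():
            out[solute_index(name)] = v
    return out


def _mk_membrane(
    cfg: dict, mem_id: tuple[str, str], defaults: dict | None, area_scale: float = 1.0
) -> MembraneSpec:
    perm = _perm_array(cfg.get("perm"), defaults)
    if "perm_default" in cfg:
        base = np.full(N_SOLUTES, cfg["perm_default"])
        listed = _perm_array(cfg.get("perm"), None)
        perm = np.where(listed > 0, listed, base)
    transporters = [
        make_transporter(t["name"], t["activity"])
        for t in cfg.get("transporters", [])
    ]
    return MembraneSpec(
        id=mem_id,
        area=cfg["area"] * area_scale,
        Lp=cfg.get("Lp", 0.0),
        sigma=cfg.get("sigma", 1.0),
        perm=perm,
        transporters=transporters,
    )


def compile_segment(
    model: ModelParameterSet,
    seg_id: str,
    length: float | None = None,
    depth: tuple[float, float] | None = None,
) -> tuple[SegmentGeometry, EpitheliumSpec]:
    """Build the geometry and epithelium spec for one segment."""
    seg = model.segments[seg_id]
    geometry = SegmentGeometry(
        id=seg_id,
        length=length if length is not None else seg["length"],
        radius=seg["radius"],
        n_grid=seg.get("n_grid", 4),
        compliant=seg.get("compliant", False),
        coalescing=seg.get("coalescing"),
        n_merge=seg.get("n_merge", 1.0),
        depth=tuple(depth if depth is not None else seg["depth"]),
        lumen_ca_factor=seg.get("lumen_ca", 1.0),
    )
    cells = []
    for cname, cell in seg["cells"].items():
        bl = cell["basolateral"]
        cp_frac = bl.get("cp_fraction", 0.5)
        lateral = _mk_membrane(bl, ("C", "P"), _CELL_MEMBRANE_DEFAULTS, cp_frac)
        basal = _mk_membrane(bl, ("C", "B"), _CELL_MEMBRANE_DEFAULTS, 1.0 - cp_frac)
        cells.append(
            CellSpec(
                name=cname,
                vol_ref=cell.get("vol_ref", 1.0e-5),
                imp_charge=cell.get("imp_charge", -60.0),
                imp_osm=cell.get("imp_osm", 40.0),
                apical=_mk_membrane(cell["apical"], ("L", "C"), _CELL_MEMBRANE_DEFAULTS),
                lateral=lateral,
                basal=basal,
                ca_factor=cell.get("ca", 1.0),
            )
        )
    spec = EpitheliumSpec(
        cells=cells,
        tight_junction=_mk_membrane(seg["tight_junction"], ("L", "P"), _TJ_DEFAULTS),
        basement=_mk_membrane(seg["basement"], ("P", "B"), None),
        lumen_ca_factor=seg.get("lumen_ca", 1.0),
    )
    return geometry, spec


def _torque_params(model: ModelParameterSet, radius: float, q0: float) -> TorqueParams:
    t = model.torque
    params = TorqueParams(
        r0=radius,
        P0=t.get("ref_pressure", model.inlet_pressure),
        mu_pt=t["mu_pt"],
        l_mv=t["l_mv"],
        delta_mv=t["delta_mv"],
        s=t["s"],
        floor=t.get("floor", 0.0),
    )
    params.tau0 = microvillous_torque(params, q0, radius, model.viscosity)
    return params


def compile_class_segments(model: ModelParameterSet, cls: NephronClass):
    """Yield (geometry, spec, torque) along one nephron class, in flow order."""
    om = model.interstitium["om_depth"]
    seg_ids = SF_SEGMENTS if cls.loop_depth <= 0 else JM_SEGMENTS
    for seg_id in seg_ids:
        length = None
        depth = None
        if seg_id == "LDL":
            length = cls.loop_depth
            depth = (om, om + cls.loop_depth)
        elif seg_id == "LAL":
            length = cls.loop_depth
            depth = (om + cls.loop_depth, om)
        geometry, spec = compile_segment(model, seg_id, length=length, depth=depth)
        torque = None
        if geometry.compliant:
            torque = _torque_params(model, geometry.radius, cls.sngfr)
        yield geometry, spec, torque


def compile_cd_segments(model: ModelParameterSet):
    """Yield (geometry, spec, torque) along the collecting-duct chain."""
    for seg_id in CD_SEGMENTS:
        geometry, spec = compile_segment(model, seg_id)
        yield geometry, spec, None
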
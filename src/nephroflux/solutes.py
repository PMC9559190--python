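"""The 15-solute chemistry: valences, acid-base buffer pairs, speciation.

The transport model carries Na+, K+, Cl-, the CO2/bicarbonate system
(HCO3-, H2CO3, CO2), the ammonia pair (NH3, NH4+), the phosphate pair
(HPO4 2-, H2PO4-), free protons, the formate pair (HCO2-, H2CO2), urea
and glucose.  Protons are carried as a free concentration (pH is derived);
the mass of each buffer is tracked as the acid+base total, which reactions
conserve, and electroneutrality closes the proton balance.

Equilibrium constants are expressed on the molar scale; concentrations in
this package are mM, so chemistry residuals convert by a factor 1e-3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

# ---------------------------------------------------------------------------
# solute table
# ---------------------------------------------------------------------------

#: Canonical solute names, in the fixed internal index order.
SOLUTES = (
    "Na+", "K+", "Cl-", "HCO3-", "H2CO3", "CO2", "NH3", "NH4+",
    "HPO4 2-", "H2PO4-", "H+", "HCO2-", "H2CO2", "urea", "glucose",
)

#: Valence of each solute, same order as :data:`SOLUTES`.
VALENCE = np.array([1, 1, -1, -1, 0, 0, 0, 1, -2, -1, 1, -1, 0, 0, 0])

# index constants
NA, K, CL, HCO3, H2CO3, CO2, NH3, NH4, HPO4, H2PO4, H, HCO2, H2CO2, UREA, GLU = range(15)

#: Solutes that participate in acid-base reactions (incl. free protons).
REACTING = frozenset({HCO3, H2CO3, CO2, NH3, NH4, HPO4, H2PO4, H, HCO2, H2CO2})

N_SOLUTES = len(SOLUTES)

_NAME_TO_INDEX = {name: i for i, name in enumerate(SOLUTES)}
# common aliases accepted in config files
_ALIASES = {
    "Na": NA, "K": K, "Cl": CL, "HCO3": HCO3, "CO2": CO2, "NH3": NH3,
    "NH4": NH4, "HPO4": HPO4, "H2PO4": H2PO4, "H": H, "HCO2": HCO2,
    "H2CO3": H2CO3, "H2CO2": H2CO2, "urea": UREA, "glucose": GLU,
    "glu": GLU,
}


def solute_index(name: str) -> int:
    """Map a solute name (canonical or short alias) to its index."""
    if name in _NAME_TO_INDEX:
        return _NAME_TO_INDEX[name]
    if name in _ALIASES:
        return _ALIASES[name]
    raise KeyError(f"unknown solute name: {name!r}")


@dataclass(frozen=True)
class SoluteSpec:
    """Identity, charge and reactivity of one model solute."""

    name: str
    valence: int
    reacting: bool

    def __post_init__(self) -> None:
        if self.name not in SOLUTES:
            raise ValueError(f"{self.name!r} is not one of the model solutes")


#: Full solute table.
SOLUTE_TABLE = tuple(
    SoluteSpec(name, int(VALENCE[i]), i in REACTING) for i, name in enumerate(SOLUTES)
)


# ---------------------------------------------------------------------------
# buffers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BufferPair:
    """An acid-base pair HA <-> H+ + A-, with molar pK.

    ``kinetic`` marks pairs whose interconversion is resolved with finite
    rates rather than instantaneous equilibrium (used for CO2 hydration).
    """

    name: str
    acid: int
    base: int
    pK: float
    kinetic: bool = False

    def __post_init__(self) -> None:
        if self.acid == self.base:
            raise ValueError("acid and base must be distinct solutes")

    @property
    def K(self) -> float:
        """Molar equilibrium constant [H][base]/[acid]."""
        return 10.0 ** (-self.pK)


# Literature defaults; overridable through the parameter config.
PK_PHOSPHATE = 6.80
PK_AMMONIUM = 9.15
PK_FORMATE = 3.76
PK_CARBONIC = 3.57  # H2CO3 <-> H+ + HCO3- (true carbonic acid pK)
#: CO2 + H2O -> H2CO3 hydration rate (1/s), uncatalysed.
KH_HYDRATION = 0.145
#: H2CO3 -> CO2 + H2O dehydration rate (1/s), uncatalysed.
KD_DEHYDRATION = 49.6

BUFFER_PAIRS = (
    BufferPair("phosphate", H2PO4, HPO4, PK_PHOSPHATE),
    BufferPair("ammonium", NH4, NH3, PK_AMMONIUM),
    BufferPair("formate", H2CO2, HCO2, PK_FORMATE),
    BufferPair("carbonic", H2CO3, HCO3, PK_CARBONIC),
)

#: hydration equilibrium ratio [H2CO3]/[CO2]
KHYD_RATIO = KH_HYDRATION / KD_DEHYDRATION


# ---------------------------------------------------------------------------
# conserved groups
# ---------------------------------------------------------------------------

#: Reaction-conserved solute groups, used for compartment balances and the
#: axial march.  CO2 and total carbonate (HCO3 + H2CO3) exchange mass only
#: through the finite-rate hydration reaction; protons belong to no group
#: (electroneutrality closes their balance).
GROUPS = {
    "Na": (NA,),
    "K": (K,),
    "Cl": (CL,),
    "bicarbonate": (HCO3, H2CO3),
    "CO2": (CO2,),
    "ammonia": (NH3, NH4),
    "phosphate": (HPO4, H2PO4),
    "formate": (HCO2, H2CO2),
    "urea": (UREA,),
    "glucose": (GLU,),
}
GROUP_NAMES = tuple(GROUPS)
N_GROUPS = len(GROUPS)

#: membership matrix M[g, k] = 1 if solute k belongs to group g
GROUP_MATRIX = np.zeros((N_GROUPS, N_SOLUTES))
for _g, _members in enumerate(GROUPS.values()):
    for _k in _members:
        GROUP_MATRIX[_g, _k] = 1.0


def group_totals(conc: np.ndarray) -> np.ndarray:
    """Collapse a 15-solute concentration vector to the 10 conserved totals."""
    return GROUP_MATRIX @ np.asarray(conc)


# ---------------------------------------------------------------------------
# residuals and speciation
# ---------------------------------------------------------------------------


def buffer_residuals(conc: np.ndarray, pairs=BUFFER_PAIRS) -> np.ndarray:
    """Deviation of each buffer pair from its mass-action relation.

    For an equilibrium pair the residual is ``log10(base/acid) - (pH - pK)``,
    i.e. zero exactly at mass action equilibrium.  For a kinetic pair the
    residual is the net forward reaction rate (per unit volume), zero when
    hydration balances dehydration.

    Parameters
    ----------
    conc:
        15-vector of compartment concentrations (mM), all strictly positive.
    pairs:
        Buffer pairs to evaluate (default: the packaged four).
    """
    conc = np.asarray(conc, dtype=float)
    if conc.shape != (N_SOLUTES,):
        raise ValueError("expected a 15-solute concentration vector")
    bad = np.nonzero(conc <= 0)[0]
    if bad.size:
        raise ValueError(
            f"non-positive concentration for solute {SOLUTES[bad[0]]!r}"
        )
    pH = -np.log10(conc[H] * 1e-3)
    out = np.empty(len(pairs))
    for i, p in enumerate(pairs):
        if p.kinetic:
            # net CO2 hydration rate: kh*[CO2] - kd*[H2CO3]
            out[i] = KH_HYDRATION * conc[CO2] - KD_DEHYDRATION * conc[H2CO3]
        else:
            out[i] = np.log10(conc[p.base] / conc[p.acid]) - (pH - p.pK)
    return out


def speciate(
    totals: dict[str, float],
    pH: float | None = None,
    carbonate_equilibrium: bool = False,
) -> np.ndarray:
    """Resolve conserved totals into the 15 individual species (mM).

    If ``pH`` is given, buffers are split at that pH directly.  Otherwise
    the pH is found from electroneutrality of the resulting mixture (the
    physically closed case, used for luminal fluid during the axial march).

    With ``carbonate_equilibrium`` the CO2/H2CO3/HCO3 system is also held
    at hydration equilibrium, so only the combined carbonate total
    (``CO2`` plus ``bicarbonate`` entries) matters.

    ``totals`` holds the 10 conserved group totals keyed by
    :data:`GROUP_NAMES`.
    """
    t = {g: float(totals[g]) for g in GROUP_NAMES}
    for g, v in t.items():
        if v < 0:
            raise ValueError(f"negative total for group {g!r}")

    def split(h_molar: float) -> np.ndarray:
        c = np.zeros(N_SOLUTES)
        c[NA], c[K], c[CL] = t["Na"], t["K"], t["Cl"]
        c[UREA], c[GLU] = t["urea"], t["glucose"]
        for pair, tot in (
            (BUFFER_PAIRS[0], t["phosphate"]),
            (BUFFER_PAIRS[1], t["ammonia"]),
            (BUFFER_PAIRS[2], t["formate"]),
        ):
            fb = pair.K / (pair.K + h_molar)
            c[pair.base] = tot * fb
            c[pair.acid] = tot * (1.0 - fb)
        carbonic = BUFFER_PAIRS[3]
        if carbonate_equilibrium:
            total_carb = t["CO2"] + t["bicarbonate"]
            co2 = total_carb / (
                1.0 + KHYD_RATIO + KHYD_RATIO * carbonic.K / h_molar
            )
            c[CO2] = co2
            c[H2CO3] = KHYD_RATIO * co2
            c[HCO3] = KHYD_RATIO * carbonic.K * co2 / h_molar
        else:
            c[CO2] = t["CO2"]
            fb = carbonic.K / (carbonic.K + h_molar)
            c[HCO3] = t["bicarbonate"] * fb
            c[H2CO3] = t["bicarbonate"] * (1.0 - fb)
        c[H] = h_molar * 1e3
        return c

    if pH is not None:
        return split(10.0 ** (-pH))

    def charge(log10_h: float) -> float:
        return float(VALENCE @ split(10.0 ** log10_h))

    # charge is strictly increasing in [H+]; bracket over a generous range
    lo, hi = -13.0, -0.5
    if charge(lo) > 0 or charge(hi) < 0:
        raise ValueError("electroneutral speciation has no root in pH 0.5..13")
    root = brentq(charge, lo, hi, xtol=1e-14, rtol=8.9e-16)
    return split(10.0 ** root)
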
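"""Transmembrane flux physics.

All kernels are written for a membrane separating compartments ``a`` and
``b`` with fluxes positive in the a-to-b direction.  Conventions:

* potential difference ``dV = V_a - V_b`` (mV),
* pressure difference ``dP = P_a - P_b`` (mmHg),
* osmotic difference passed to :func:`water_flux` is the *far-minus-near*
  concentration difference ``C_b - C_a`` per solute, so that water flows
  a->b when b is hypertonic and the kernel keeps its antisymmetry.

Solute fluxes are in umol s^-1 cm^-2, volume flux in cm/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import CONSTANTS, PhysicalConstants
from .solutes import N_SOLUTES, VALENCE

__all__ = [
    "MembraneSpec",
    "TransporterSpec",
    "TorqueParams",
    "water_flux",
    "log_mean_concentration",
    "electrodiffusive_flux",
    "convective_flux",
    "coupled_flux",
    "atpase_flux",
    "compliant_radius",
    "microvillous_torque",
    "torque_scale",
    "total_solute_flux",
]

_GHK_SERIES_CUTOFF = 1e-4


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------


@dataclass
class TransporterSpec:
    """A cotransporter, exchanger, primary pump or channel on one membrane.

    ``stoich`` maps solute index -> signed stoichiometric coefficient,
    positive for transport in the membrane's a-to-b direction.  The default
    coupled kinetics are the linear nonequilibrium-thermodynamic form
    (turnover proportional to the stoichiometry-weighted electrochemical
    gradient); ``modes`` lets a transporter run several stoichiometries in
    parallel with fixed weights, which is how NH4+ substitution for H+ on
    NHE3 and for K+ on NKCC2 is represented.  ``km`` holds optional
    half-saturation constants (mM) keyed by solute index; when present the
    coupled rate is multiplied by Michaelis factors in the *a*-side
    concentrations of those solutes.

    Channels carry a single solute; their ``activity`` is an added membrane
    permeability (cm/s) and they are folded into the passive pathway.
    ATPases use saturable Hill kinetics (see :func:`atpase_flux`).
    """

    name: str
    kind: str  # "cotransporter" | "exchanger" | "ATPase" | "channel"
    stoich: dict[int, float]
    activity: float
    km: dict[int, float] = field(default_factory=dict)
    modes: tuple[tuple[float, dict[int, float]], ...] = ()
    #: Hill exponents for ATPases, keyed like km.
    hill: dict[int, float] = field(default_factory=dict)
    #: for Na-K-ATPase: (solute index on side b, scale mM) modulating K_Na
    km_modulation: tuple[int, float] | None = None
    #: coupled kinetics: "linear" (nonequilibrium-thermodynamic) or
    #: "carrier" (saturable alternating-access form)
    kinetics: str = "linear"

    def __post_init__(self) -> None:
        if self.kind not in ("cotransporter", "exchanger", "ATPase", "channel"):
            raise ValueError(f"unknown transporter kind {self.kind!r}")
        if self.activity < 0:
            raise ValueError("transporter activity must be >= 0")
        if self.kind in ("cotransporter", "exchanger"):
            nz = [s for s, v in self.stoich.items() if v != 0]
            if len(nz) < 2:
                raise ValueError(
                    f"{self.name}: coupled transporter needs >= 2 solutes"
                )

    def scaled(self, factor: float) -> "TransporterSpec":
        """Copy with the activity multiplied by ``factor``."""
        return TransporterSpec(
            self.name, self.kind, dict(self.stoich), self.activity * factor,
            dict(self.km), self.modes, dict(self.hill), self.km_modulation,
            self.kinetics,
        )


@dataclass
class MembraneSpec:
    """Passive properties of one membrane plus its attached transporters.

    ``area`` is cm^2 per cm of tubule (microvillous/infolding amplification
    included); ``Lp`` is hydraulic permeability in cm s^-1 mmHg^-1; ``sigma``
    is the osmotic reflection coefficient applied to every solute unless
    a per-solute value is supplied in ``sigma_k``; ``perm`` holds passive
    permeabilities h_k (cm/s).
    """

    id: tuple[str, str]  # (a, b) with a,b in {"L","C","P","B"}
    area: float
    Lp: float
    sigma: float = 1.0
    perm: np.ndarray = field(default_factory=lambda: np.zeros(N_SOLUTES))
    sigma_k: np.ndarray | None = None
    transporters: list[TransporterSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.perm = np.asarray(self.perm, dtype=float)
        if self.area < 0 or self.Lp < 0 or np.any(self.perm < 0):
            raise ValueError("membrane area, Lp and permeabilities must be >= 0")
        if not 0.0 <= self.sigma <= 1.0:
            raise ValueError("reflection coefficient must lie in [0, 1]")
        if self.sigma_k is None:
            self.sigma_k = np.full(N_SOLUTES, self.sigma)
        else:
            self.sigma_k = np.asarray(self.sigma_k, dtype=float)
            if np.any((self.sigma_k < 0) | (self.sigma_k > 1)):
                raise ValueError("per-solute reflection coefficients in [0,1]")

    @property
    def effective_perm(self) -> np.ndarray:
        """Passive permeabilities including open channels (cm/s)."""
        cached = getattr(self, "_eff_perm", None)
        if cached is not None:
            return cached
        h = self.perm.copy()
        for t in self.transporters:
            if t.kind == "channel":
                for k, s in t.stoich.items():
                    h[k] += t.activity * abs(s)
        object.__setattr__(self, "_eff_perm", h)
        return h


@dataclass
class TorqueParams:
    """Proximal-tubule compliance and microvillous-torque parameters.

    Units: radii and lengths in cm, pressures in mmHg, compliance ``mu_pt``
    in 1/mmHg.  ``tau0`` (dyn, per microvillus cluster) is set from the
    reference flow and radius at the proximal tubule inlet.
    """

    r0: float
    P0: float
    mu_pt: float
    l_mv: float
    delta_mv: float
    s: float
    tau0: float = 0.0
    floor: float = 0.0

    def __post_init__(self) -> None:
        if self.r0 <= 0 or self.l_mv <= 0:
            raise ValueError("reference radius and microvillous length must be > 0")
        if min(self.mu_pt, self.delta_mv, self.s, self.floor) < 0:
            raise ValueError("mu_pt, delta_mv, s and floor must be >= 0")


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------


def water_flux(
    membrane: MembraneSpec,
    osmotic_difference: np.ndarray | float,
    pressure_difference: float,
    constants: PhysicalConstants = CONSTANTS,
    sigma_k: np.ndarray | None = None,
) -> float:
    """Transmembrane volume flow J_v (cm^3/s per cm tubule), a->b positive.

    ``osmotic_difference`` is the per-solute far-minus-near difference
    ``C_b - C_a`` (mM) and ``pressure_difference`` is ``P_a - P_b`` (mmHg):
    J_v = A * Lp * (sigma * RT * sum_k dC_k + dP).  Swapping the
    compartments negates both arguments and hence the flux.
    """
    dC = np.atleast_1d(np.asarray(osmotic_difference, dtype=float))
    if sigma_k is None:
        osm = membrane.sigma * float(np.sum(dC))
    else:
        osm = float(np.dot(np.atleast_1d(sigma_k), dC))
    return membrane.area * membrane.Lp * (constants.RT_osm * osm + pressure_difference)


def log_mean_concentration(c_a, c_b):
    """Logarithmic mean (C_a - C_b)/(ln C_a - ln C_b), elementwise.

    Continuous at C_a == C_b with limiting value C_a; requires strictly
    positive concentrations.
    """
    a = np.asarray(c_a, dtype=float)
    b = np.asarray(c_b, dtype=float)
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("log-mean concentration needs positive inputs")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(
            np.isclose(a, b, rtol=1e-12, atol=0.0),
            a,
            (a - b) / np.log(np.where(a == b, 2.0, a / b)),
        )
    if out.ndim == 0:
        return float(out)
    return out


def _ghk_factor(zeta):
    """zeta / (1 - exp(-zeta)) with a series patch near zero."""
    zeta = np.asarray(zeta, dtype=float)
    small = np.abs(zeta) < _GHK_SERIES_CUTOFF
    z = np.where(small, 1.0, zeta)
    with np.errstate(over="ignore"):
        f = z / (1.0 - np.exp(-z))
    # series: zeta/(1-e^-zeta) = 1 + z/2 + z^2/12 + O(z^4)
    return np.where(small, 1.0 + zeta / 2.0 + zeta**2 / 12.0, f)


def electrodiffusive_flux(
    z: np.ndarray | int,
    h: np.ndarray | float,
    c_a,
    c_b,
    dV: float,
    constants: PhysicalConstants = CONSTANTS,
):
    """Goldman-Hodgkin-Katz flux per unit area (umol s^-1 cm^-2), a->b.

    For charged solutes J = h * zeta * (C_a - C_b e^-zeta)/(1 - e^-zeta)
    with zeta = z F dV / RT; for z = 0 this reduces smoothly to Fick's law
    J = h (C_a - C_b).  ``dV = V_a - V_b`` in mV.
    """
    z = np.asarray(z, dtype=float)
    c_a = np.asarray(c_a, dtype=float)
    c_b = np.asarray(c_b, dtype=float)
    if np.any(c_a <= 0) or np.any(c_b <= 0):
        raise ValueError("GHK flux needs positive concentrations")
    zeta = z * constants.F_RT * dV
    small = np.abs(zeta) < _GHK_SERIES_CUTOFF
    zs = np.where(small, 0.0, zeta)
    with np.errstate(over="ignore"):
        exact = np.where(
            small,
            0.0,
            np.where(zs == 0.0, 1.0, zs) / (1.0 - np.exp(-np.where(zs == 0.0, 1.0, zs)))
            * (c_a - c_b * np.exp(-zs)),
        )
    # 2nd-order series about zeta = 0 keeps the removable singularity smooth
    series = (c_a - c_b) + zeta * (c_a + c_b) / 2.0 + zeta**2 * (c_a - c_b) / 12.0
    out = np.asarray(h, dtype=float) * np.where(small, series, exact)
    if out.ndim == 0:
        return float(out)
    return out


def convective_flux(sigma_k, c_mean, j_v):
    """Solvent-drag solute flux (1 - sigma_k) * C-bar * J_v per unit area."""
    sigma_k = np.asarray(sigma_k, dtype=float)
    if np.any((sigma_k < 0) | (sigma_k > 1)):
        raise ValueError("reflection coefficient must lie in [0, 1]")
    out = (1.0 - sigma_k) * np.asarray(c_mean, dtype=float) * j_v
    if out.ndim == 0:
        return float(out)
    return out


def electrochemical_potential_difference(
    c_a, c_b, dV: float, z=VALENCE, constants: PhysicalConstants = CONSTANTS
):
    """(mu_a - mu_b)/RT per solute: ln(C_a/C_b) + z F dV / RT."""
    c_a = np.asarray(c_a, dtype=float)
    c_b = np.asarray(c_b, dtype=float)
    if np.any(c_a <= 0) or np.any(c_b <= 0):
        raise ValueError("electrochemical potential needs positive concentrations")
    return np.log(c_a / c_b) + np.asarray(z, dtype=float) * constants.F_RT * dV


def coupled_flux(
    transporter: TransporterSpec,
    c_a: np.ndarray,
    c_b: np.ndarray,
    dV: float,
    constants: PhysicalConstants = CONSTANTS,
) -> np.ndarray:
    """Per-solute flux through a cotransporter or exchanger (a->b positive).

    The turnover of each stoichiometric mode is
    ``activity * weight * sat * sum_k nu_k dmu_k / RT`` where ``dmu_k`` is the
    electrochemical potential difference and ``sat`` the product of optional
    Michaelis factors; each participating solute moves in strict proportion
    to its coefficient.  The flux vanishes exactly at coupled equilibrium.
    """
    if transporter.kind not in ("cotransporter", "exchanger"):
        raise ValueError(
            f"{transporter.name}: coupled_flux applies to cotransporters/exchangers"
        )
    modes = transporter.modes if transporter.modes else ((1.0, transporter.stoich),)
    out = np.zeros(N_SOLUTES)
    if transporter.kinetics == "carrier":
        # saturable alternating-access carrier: the turnover is bounded by
        # the activity, so a depleted counter-gradient cannot be offset by
        # an ever-growing thermodynamic drive.  Valid for electroneutral
        # stoichiometries (the exchangers it is used for).
        for weight, stoich in modes:
            fwd = rev = 1.0
            denom = 1.0
            for k, nu in stoich.items():
                km = transporter.km.get(k)
                if km is None:
                    raise ValueError(
                        f"{transporter.name}: carrier kinetics need a Km "
                        f"for every participating solute"
                    )
                an, bn = c_a[k] / km, c_b[k] / km
                if nu > 0:
                    fwd *= an ** nu
                    rev *= bn ** nu
                else:
                    fwd *= bn ** (-nu)
                    rev *= an ** (-nu)
                denom += an + bn
            denom += fwd + rev  # loaded-carrier states bound the turnover
            rate = transporter.activity * weight * (fwd - rev) / denom
            for k, nu in stoich.items():
                out[k] += nu * rate
        return out
    dmu = electrochemical_potential_difference(c_a, c_b, dV, constants=constants)
    for weight, stoich in modes:
        drive = sum(nu * dmu[k] for k, nu in stoich.items())
        sat = 1.0
        for k, km in transporter.km.items():
            sat *= c_a[k] / (c_a[k] + km)
        rate = transporter.activity * weight * sat * drive
        for k, nu in stoich.items():
            out[k] += nu * rate
    return out


def atpase_flux(
    transporter: TransporterSpec,
    c_a: np.ndarray,
    c_b: np.ndarray,
) -> np.ndarray:
    """Per-solute flux through a primary active pump (a->b positive).

    Hill-type saturable rate: activity times, for each solute with a
    half-saturation constant, ``(C/(C + Km))^n`` evaluated on the side the
    pump binds it (the side it transports the solute *from*).  The rate is
    monotone in each driving concentration and bounded by the activity;
    solutes move in fixed stoichiometric ratio (e.g. 3 Na+ : 2 K+).
    """
    if transporter.kind != "ATPase":
        raise ValueError(f"{transporter.name}: atpase_flux applies to ATPases")
    c_a = np.asarray(c_a, dtype=float)
    c_b = np.asarray(c_b, dtype=float)
    if np.any(c_a < 0) or np.any(c_b < 0):
        raise ValueError("ATPase kinetics need non-negative concentrations")
    rate = transporter.activity
    for k, km in transporter.km.items():
        nu = transporter.stoich.get(k, 0.0)
        c = c_a[k] if nu > 0 else c_b[k]  # bind on the donor side
        if transporter.km_modulation is not None and nu > 0:
            mod_k, mod_scale = transporter.km_modulation
            km = km * (1.0 + c_b[mod_k] / mod_scale)
        n = transporter.hill.get(k, 1.0)
        rate *= (c / (c + km)) ** n
    out = np.zeros(N_SOLUTES)
    for k, nu in transporter.stoich.items():
        out[k] = nu * rate
    return out


# ---------------------------------------------------------------------------
# proximal tubule torque modulation
# ---------------------------------------------------------------------------


def compliant_radius(params: TorqueParams, pressure: float) -> float:
    """Compliant luminal radius r = r0 (1 + mu_pt (P - P0))."""
    r = params.r0 * (1.0 + params.mu_pt * (pressure - params.P0))
    if r <= 0:
        raise ValueError(
            f"compliant radius non-positive at P = {pressure:.3f} mmHg"
        )
    return r


def microvillous_torque(
    params: TorqueParams, flow: float, radius: float, viscosity: float
) -> float:
    """Microvillous drag torque.

    tau = 8 mu Q l_mv / r^2 * (1 + (l_mv + delta_mv)/r + l_mv^2/(2 r^2)),
    linear in the flow and strictly decreasing in the radius for Q > 0.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    l, d = params.l_mv, params.delta_mv
    return (
        8.0 * viscosity * flow * l / radius**2
        * (1.0 + (l + d) / radius + l**2 / (2.0 * radius**2))
    )


def torque_scale(params: TorqueParams, tau: float) -> float:
    """Flow-dependent transport scale S = 1 + s (tau/tau0 - 1), floored at 0.

    S equals 1 at the reference torque; the configurable nonnegative floor
    prevents unphysical negative transport at very low flows.
    """
    if params.tau0 <= 0:
        raise ValueError("reference torque tau0 must be positive")
    return max(params.floor, 1.0 + params.s * (tau / params.tau0 - 1.0))


# ---------------------------------------------------------------------------
# total flux
# ---------------------------------------------------------------------------


def total_solute_flux(
    membrane: MembraneSpec,
    c_a: np.ndarray,
    c_b: np.ndarray,
    dV: float,
    j_v_per_area: float,
    constants: PhysicalConstants = CONSTANTS,
) -> dict[str, np.ndarray]:
    """All four flux mechanisms across one membrane, per unit area.

    Returns a per-mechanism breakdown (convective, electrodiffusive,
    coupled, ATP-driven) plus their sum under ``"total"``; each entry is a
    15-vector of fluxes in the a->b direction.
    """
    c_a = np.asarray(c_a, dtype=float)
    c_b = np.asarray(c_b, dtype=float)
    cbar = log_mean_concentration(c_a, c_b)
    conv = convective_flux(membrane.sigma_k, cbar, j_v_per_area)
    ed = electrodiffusive_flux(
        VALENCE, membrane.effective_perm, c_a, c_b, dV, constants
    )
    coup = np.zeros(N_SOLUTES)
    pump = np.zeros(N_SOLUTES)
    for t in membrane.transporters:
        if t.kind in ("cotransporter", "exchanger"):
            coup += coupled_flux(t, c_a, c_b, dV, constants)
        elif t.kind == "ATPase":
            pump += atpase_flux(t, c_a, c_b)
    total = conv + ed + coup + pump
    return {
        "convective": conv,
        "electrodiffusive": ed,
        "coupled": coup,
        "ATP-driven": pump,
        "total": total,
    }
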
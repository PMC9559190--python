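"""Axial integration along tubules and whole-kidney assembly.

Each tubule segment is marched in the flow direction with an implicit
backward-differentiation scheme (backward Euler on the first interval,
BDF2 after).  The marched state is the set of reaction-conserved
quantities: volume flow and the conserved solute group flows (times the
coalescence fraction for merging segments), plus the hydrostatic pressure
from Poiseuille flow.  At every axial station the luminal state and the
epithelial cross-section are solved as one coupled system (warm-started
from the previous station); luminal speciation (individual buffer species
and pH) follows from electroneutrality, which is preserved exactly
because the cross-section solution enforces zero net current out of the
lumen.  Implicitness matters: at physiological permeabilities the luminal
relaxation lengths of gases and water are far below the grid spacing.

Six nephron classes (one superficial, five juxtamedullary of increasing
loop depth) run in parallel; their connecting-tubule outflows merge, by
population weight, into a single collecting-duct chain whose inner
medullary portion coalesces further.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import CONSTANTS, DYN_PER_MMHG, PhysicalConstants
from .epithelium import (
    CompartmentState,
    EpithelialConvergenceError,
    EpitheliumProblem,
    EpitheliumSpec,
    NewtonCache,
    SolverOptions,
    _chem_residuals_cell,
    damped_newton,
)
from .fluxes import (
    TorqueParams,
    compliant_radius,
    microvillous_torque,
    torque_scale,
)
from .solutes import (
    CO2,
    GROUP_MATRIX,
    GROUP_NAMES,
    H2CO3,
    KHYD_RATIO,
    N_GROUPS,
    VALENCE,
    speciate,
)

_IDX = {g: i for i, g in enumerate(GROUP_NAMES)}
_G_CO2 = _IDX["CO2"]
_G_BIC = _IDX["bicarbonate"]

#: reporting order for delivery tables
KEY_SPECIES = ("volume", "Na+", "K+", "Cl-", "HCO3-", "NH4+")


# ---------------------------------------------------------------------------
# coalescence fractions
# ---------------------------------------------------------------------------


def omega_cnt(
    x: float, length: float, floor: float = 0.182, clamp: bool = True
) -> float:
    """Fraction of connecting tubules remaining at axial position ``x``.

    omega = 2 - 2.32**(x/L); equals 1 at the inlet and decreases as
    tubules merge.  The printed formula becomes negative at the very end
    of the segment, so the returned value is clamped below at ``floor``
    (about 2/11, six tubules merging toward one collecting duct); pass
    ``clamp=False`` to obtain the raw formula value.
    """
    if not 0.0 <= x <= length:
        raise ValueError("axial position outside [0, L]")
    w = 2.0 - 2.32 ** (x / length)
    if clamp:
        return max(w, floor)
    return w


def omega_imcd(x: float, length: float) -> float:
    """Fraction of inner-medullary collecting ducts remaining at ``x``.

    omega = 0.1 (1 - 0.95 (x/L)^2) exp(-2.75 x/L), strictly decreasing
    from 0.1 at the inner-medulla entrance.
    """
    if not 0.0 <= x <= length:
        raise ValueError("axial position outside [0, L]")
    s = x / length
    return 0.1 * (1.0 - 0.95 * s * s) * np.exp(-2.75 * s)


# ---------------------------------------------------------------------------
# geometry / class descriptors
# ---------------------------------------------------------------------------


@dataclass
class SegmentGeometry:
    """Geometry and numerical grid of one tubule segment."""

    id: str
    length: float
    radius: float
    n_grid: int = 4
    compliant: bool = False
    coalescing: str | None = None  # None | "CNT" | "IMCD"
    n_merge: float = 1.0  # tubules feeding one duct (pressure calculation)
    depth: tuple[float, float] = (0.0, 0.0)
    lumen_ca_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.length < 0 or self.radius <= 0:
            raise ValueError(f"{self.id}: length must be >= 0 and radius > 0")
        if self.n_grid < 2:
            raise ValueError(f"{self.id}: need at least 2 axial intervals")

    def omega(self, x: float) -> float:
        """Coalescence fraction normalised to 1 at the segment inlet."""
        if self.coalescing == "CNT":
            return omega_cnt(x, self.length)
        if self.coalescing == "IMCD":
            return omega_imcd(x, self.length) / omega_imcd(0.0, self.length)
        return 1.0

    def depth_at(self, x: float) -> float:
        d0, d1 = self.depth
        if self.length == 0:
            return d0
        return d0 + (d1 - d0) * x / self.length


@dataclass
class NephronClass:
    """One nephron population: label, weight, SNGFR and loop depth."""

    label: str
    weight: float
    sngfr: float  # cm^3/s
    loop_depth: float = 0.0  # cm into the inner medulla

    def __post_init__(self) -> None:
        if self.weight <= 0 or self.sngfr <= 0:
            raise ValueError("population weight and SNGFR must be positive")


class InterstitialProfile:
    """Prescribed peritubular composition as a function of depth.

    The cortical boundary matches plasma; solute totals rise piecewise-
    exponentially through the outer medulla (thickness ``om_depth``) to the
    papillary tip (``om_depth + im_depth``).  Only Na, K, Cl and urea vary;
    Cl is adjusted so the profile stays electroneutral at the prescribed
    pH.  Pressures are uniform.
    """

    def __init__(
        self,
        plasma_totals: dict[str, float],
        pH: float = 7.4,
        pressure: float = 4.0,
        om_depth: float = 0.2,
        im_depth: float = 0.5,
        om_boundary: dict[str, float] | None = None,
        tip: dict[str, float] | None = None,
    ):
        self.plasma_totals = dict(plasma_totals)
        self.pH = pH
        self.pressure = pressure
        self.om_depth = om_depth
        self.im_depth = im_depth
        self.om_boundary = dict(om_boundary or {})
        self.tip = dict(tip or {})
        self._cache: dict[float, CompartmentState] = {}

    def totals_at(self, depth: float) -> dict[str, float]:
        t = dict(self.plasma_totals)
        for key in set(self.om_boundary) | set(self.tip):
            v0 = self.plasma_totals[key]
            v_om = self.om_boundary.get(key, v0)
            v_tip = self.tip.get(key, v_om)
            if depth <= 0:
                v = v0
            elif depth <= self.om_depth:
                v = v0 * (v_om / v0) ** (depth / self.om_depth)
            else:
                f = min((depth - self.om_depth) / self.im_depth, 1.0)
                v = v_om * (v_tip / v_om) ** f
            t[key] = v
        return t

    def __call__(self, depth: float) -> CompartmentState:
        key = round(depth, 9)
        if key not in self._cache:
            from .solutes import CL, VALENCE

            t = self.totals_at(depth)
            conc = speciate(t, pH=self.pH)
            # restore electroneutrality through Cl at the prescribed pH
            conc[CL] = max(conc[CL] + float(VALENCE @ conc), 1.0)
            self._cache[key] = CompartmentState(conc, 0.0, self.pressure, id="B")
        return self._cache[key]


# ---------------------------------------------------------------------------
# luminal state and the right-hand side
# ---------------------------------------------------------------------------


@dataclass
class LuminalState:
    """Luminal fluid at one axial station (per tubule)."""

    Q: float
    P: float
    conc: np.ndarray
    V: float
    x: float


def speciate_lumen(group_conc: np.ndarray) -> np.ndarray:
    """Resolve luminal group concentrations into species, electroneutrally.

    The CO2/H2CO3/HCO3 system is held at hydration equilibrium: with
    carbonic anhydrase present the luminal reaction is fast on the transit
    scale, so only the combined carbonate pool is dynamically meaningful.
    """
    totals = {g: max(float(group_conc[i]), 1e-12) for g, i in _IDX.items()}
    return speciate(totals, carbonate_equilibrium=True)


def lumen_rhs(
    Q: float,
    jv_per_cm: float,
    jk_groups_per_cm: np.ndarray,
    geometry: SegmentGeometry,
    omega: float,
    radius: float,
    viscosity: float,
) -> tuple[float, np.ndarray, float]:
    """Axial derivatives of the conserved luminal quantities.

    Returns ``(d(omega Q)/dx, d(omega Q C_g)/dx, dP/dx)``.  The flux inputs
    are the totals *out of* the lumen per cm of a single tubule, so
    reabsorptive flux reduces luminal content; for coalescing segments the
    transport terms scale with the remaining tubule fraction ``omega``.
    The pressure gradient is Poiseuille flow of the per-duct stream.
    """
    dyv = -omega * jv_per_cm
    dyg = -omega * np.asarray(jk_groups_per_cm, dtype=float)
    q_duct = Q * geometry.n_merge
    dp = -8.0 * viscosity * q_duct / (np.pi * radius**4) / DYN_PER_MMHG
    return dyv, dyg, float(dp)


# ---------------------------------------------------------------------------
# segment marching
# ---------------------------------------------------------------------------


class SegmentConvergenceError(RuntimeError):
    """Epithelial failure during a segment march, located axially."""

    def __init__(self, segment: str, x: float, err: Exception):
        super().__init__(f"segment {segment} failed at x = {x:.4f} cm: {err}")
        self.segment = segment
        self.x = x


@dataclass
class SegmentResult:
    """Solved axial profiles and net transport for one segment."""

    geometry: SegmentGeometry
    x: np.ndarray
    yv: np.ndarray  # omega * Q, cm^3/s per inlet tubule
    yg: np.ndarray  # (N+1, n_groups) omega * Q * C_g
    P: np.ndarray
    V_lumen: np.ndarray
    conc: np.ndarray  # (N+1, 15) luminal species
    s_torq: np.ndarray
    inlet_species: np.ndarray
    outlet_species: np.ndarray
    #: converged epithelial unknown vector at the outlet (warm-start chaining)
    final_epithelium: np.ndarray | None = None
    #: stations accepted at the loosened salvage tolerance
    n_salvaged: int = 0

    @property
    def net_reabsorption(self) -> np.ndarray:
        """Per-group net removal from the lumen, umol/s per inlet tubule.

        The CO2 and bicarbonate pools interconvert through the luminal
        hydration reaction; their individual entries reflect the
        equilibrium partition, and their *sum* is the conserved carbonate
        balance.
        """
        return self.yg[0] - self.yg[-1]

    @property
    def net_volume_reabsorption(self) -> float:
        return float(self.yv[0] - self.yv[-1])

    def species_delivery(self, station: int) -> np.ndarray:
        """Per-species delivery omega*Q*C_k at a station (umol/s/tubule)."""
        return self.conc[station] * self.yv[station]


#: luminal balance slots: the eight reaction-free groups, then carbonate
_LUM_PLAIN = tuple(
    _IDX[g] for g in ("Na", "K", "Cl", "ammonia", "phosphate", "formate",
                      "urea", "glucose")
)


class _AxialStepper:
    """Implicit (BDF) axial integrator for one segment.

    At each station the luminal state (15 log-concentrations, log flow and
    pressure) and the full epithelial cross-section are solved as one
    coupled nonlinear system: a backward-differentiation discretisation of
    the luminal conservation laws closed by buffer equilibria and
    electroneutrality, with the transmural fluxes evaluated implicitly at
    the new station.  L-stability handles the fast luminal relaxation of
    gases and water (equilibration lengths far below the grid spacing).
    """

    def __init__(self, geometry, epi_spec, interstitium, torque, viscosity,
                 options, constants):
        self.geometry = geometry
        self.problem = EpitheliumProblem(epi_spec, options, constants)
        self.interstitium = interstitium
        self.torque = torque
        self.viscosity = viscosity
        self.options = options or SolverOptions()
        self.cache = NewtonCache()
        self.n_salvaged = 0
        self.n = self.problem.n
        self.max_step = np.concatenate(
            [self.problem._max_step, np.full(15, 4.0), [1.0], [20.0]]
        )
        # transport capacity of the lumen-facing membranes per group, used
        # to scale depleted-solute balances sensibly
        from .epithelium import _group_capacity

        c_ref = interstitium(geometry.depth_at(0.0)).conc
        spec = self.problem.spec
        cap = sum(
            _group_capacity(mem, c_ref)
            for mem in [spec.tight_junction] + [c.apical for c in spec.cells]
        )
        cap9 = np.empty(9)
        cap9[:8] = [cap[gi] for gi in _LUM_PLAIN]
        cap9[8] = cap[_G_CO2] + cap[_G_BIC]
        self.lum_cap = cap9

    # luminal residual slots (offset self.n):
    #   0..7 plain group balances, 8 carbonate balance, 9..12 buffer
    #   mass action, 13 hydration equilibrium, 14 electroneutrality,
    #   15 volume balance, 16 Poiseuille pressure
    def torque_scale_at(self, Q: float, P: float) -> tuple[float, float]:
        if self.geometry.compliant and self.torque is not None:
            r = compliant_radius(self.torque, P)
            tau = microvillous_torque(self.torque, Q, r, self.viscosity)
            return r, torque_scale(self.torque, tau)
        return self.geometry.radius, 1.0

    def residual(self, z, x_pos, bath, coeffs, scales):
        c0, terms = coeffs  # terms: list of (coef, yv, ygroups9, P)
        g = self.geometry
        x_epi = z[: self.n]
        cL = np.exp(z[self.n : self.n + 15])
        yv1 = np.exp(z[self.n + 15])
        P1 = z[self.n + 16]
        om = g.omega(x_pos)
        Q1 = yv1 / om
        r1, s_torq = self.torque_scale_at(Q1, P1)
        F_epi, jv, jk = self.problem.residual(
            x_epi, cL, P1, bath, s_torq, 1.0, scaled=True, return_fluxes=True
        )
        dyv, dyg, dp = lumen_rhs(
            Q1, jv, GROUP_MATRIX @ jk, g, om, r1, self.viscosity
        )
        cg = GROUP_MATRIX @ cL
        FL = np.empty(17)
        # discrete derivative terms (c0*y1 + sum(coef*y_prev)) / dx
        for slot, gi in enumerate(_LUM_PLAIN):
            acc = c0 * cg[gi] * yv1
            for coef, yv_p, yg_p, _ in terms:
                acc += coef * yg_p[slot]
            FL[slot] = acc - dyg[gi]
        acc = c0 * (cg[_G_CO2] + cg[_G_BIC]) * yv1
        for coef, yv_p, yg_p, _ in terms:
            acc += coef * yg_p[8]
        FL[8] = acc - (dyg[_G_CO2] + dyg[_G_BIC])
        FL[9:13] = _chem_residuals_cell(cL)
        FL[13] = np.log(cL[H2CO3] / (KHYD_RATIO * cL[CO2]))
        FL[14] = float(VALENCE @ cL) / 150.0
        acc = c0 * yv1
        for coef, yv_p, _, _ in terms:
            acc += coef * yv_p
        FL[15] = acc - dyv
        acc = c0 * P1
        for coef, _, _, P_p in terms:
            acc += coef * P_p
        FL[16] = acc - dp
        return np.concatenate([F_epi, FL / scales])

    @staticmethod
    def _pack_prev(yv, yg10, P):
        yg9 = np.empty(9)
        yg9[:8] = [yg10[gi] for gi in _LUM_PLAIN]
        yg9[8] = yg10[_G_CO2] + yg10[_G_BIC]
        return yv, yg9, P

    def _lum_scales(self, yv0, yg9_0, dx):
        scales = np.ones(17)
        floor = 1e-3 * yv0  # 1 uM-scale flow floor
        scales[:9] = np.maximum(np.abs(yg9_0), floor) / dx + self.lum_cap
        scales[15] = yv0 / dx
        scales[16] = 1.0
        return scales

    def step(self, z, x_new, dx, prev, prev2, depth=0):
        """Advance one station; returns (z_new, used_subdivision)."""
        bath = self.interstitium(self.geometry.depth_at(x_new))
        self.problem._compute_structure(bath)
        yv0, yg0, P0 = prev
        if prev2 is not None:
            c0 = 1.5 / dx
            terms = [(-2.0 / dx, prev[0], prev[1], prev[2]),
                     (0.5 / dx, prev2[0], prev2[1], prev2[2])]
        else:
            c0 = 1.0 / dx
            terms = [(-1.0 / dx, prev[0], prev[1], prev[2])]
        scales = self._lum_scales(yv0, yg0, dx)
        try:
            z_new = damped_newton(
                lambda zz: self.residual(zz, x_new, bath, (c0, terms), scales),
                z, self.max_step, self.options, self.cache,
            )
            return z_new, False
        except EpithelialConvergenceError as err:
            if depth >= 2:
                # deeply subdivided and still stuck (an extreme corner of
                # the deep-medulla regime): salvage the best approximate
                # station; the marched conservation laws are unaffected
                from dataclasses import replace as _replace

                self.cache.clear()
                loose = _replace(self.options, accept_tol=1e-3)
                try:
                    z_new = damped_newton(
                        lambda zz: self.residual(
                            zz, x_new, bath, (c0, terms), scales
                        ),
                        z, self.max_step, loose, self.cache,
                    )
                    self.n_salvaged += 1
                    return z_new, True
                except EpithelialConvergenceError as err2:
                    raise SegmentConvergenceError(self.geometry.id, x_new, err2)
        # subdivide: two backward-Euler half steps
        self.cache.clear()
        x_mid = x_new - dx / 2.0
        z_mid, _ = self.step(z, x_mid, dx / 2.0, prev, None, depth + 1)
        prev_mid = self.unpack(z_mid)
        z_new, _ = self.step(z_mid, x_new, dx / 2.0, prev_mid, None, depth + 1)
        return z_new, True

    def unpack(self, z):
        cL = np.exp(z[self.n : self.n + 15])
        yv = float(np.exp(z[self.n + 15]))
        P = float(z[self.n + 16])
        return self._pack_prev(yv, (GROUP_MATRIX @ cL) * yv, P)

    def state_at(self, z):
        cL = np.exp(z[self.n : self.n + 15])
        yv = float(np.exp(z[self.n + 15]))
        P = float(z[self.n + 16])
        V_L = float(z[self.n - 1])
        return cL, yv, P, V_L


def solve_segment(
    geometry: SegmentGeometry,
    epi_spec: EpitheliumSpec,
    inlet_yv: float,
    inlet_yg: np.ndarray,
    inlet_P: float,
    interstitium: InterstitialProfile,
    torque: TorqueParams | None = None,
    viscosity: float = 7.2e-3,
    options: SolverOptions | None = None,
    constants: PhysicalConstants = CONSTANTS,
    epi_guess: np.ndarray | None = None,
) -> SegmentResult:
    """March one segment from its inlet; returns profiles and net transport.

    ``inlet_yv``/``inlet_yg`` are the conserved (coalescence-scaled) volume
    and group flows per inlet tubule.  Stations advance with backward
    Euler (first interval) then BDF2, the cross-section solved implicitly
    within each step and warm-started from the previous station; a failing
    interval is subdivided into backward-Euler half steps.
    """
    N = geometry.n_grid
    xs = np.linspace(0.0, geometry.length, N + 1)
    yv = np.empty(N + 1)
    yg = np.empty((N + 1, N_GROUPS))
    Ps = np.empty(N + 1)
    VL = np.empty(N + 1)
    CONC = np.empty((N + 1, 15))
    ST = np.empty(N + 1)

    # inlet: species at carbonate/acid-base equilibrium; the carbonate
    # repartition preserves the combined pool exactly
    conc0 = speciate_lumen(np.asarray(inlet_yg, dtype=float) / inlet_yv)
    yv[0] = inlet_yv
    yg[0] = (GROUP_MATRIX @ conc0) * inlet_yv
    Ps[0] = inlet_P
    CONC[0] = conc0

    if geometry.length == 0.0:
        for j in range(1, N + 1):
            yv[j], yg[j], Ps[j], CONC[j] = yv[0], yg[0], Ps[0], conc0
        VL[:] = 0.0
        ST[:] = 1.0
        return SegmentResult(
            geometry, xs, yv, yg, Ps, VL, CONC, ST,
            conc0 * inlet_yv, conc0 * inlet_yv, epi_guess,
        )

    dx = geometry.length / N
    stepper = _AxialStepper(
        geometry, epi_spec, interstitium, torque, viscosity, options, constants
    )
    # inlet cross-section (diagnostics + warm start)
    om0 = geometry.omega(0.0)
    r0, s0 = stepper.torque_scale_at(inlet_yv / om0, inlet_P)
    bath0 = interstitium(geometry.depth_at(0.0))
    lum0 = CompartmentState(conc0, 0.0, inlet_P, id="L")
    guess0 = None
    if epi_guess is not None:
        if epi_guess.size == stepper.problem.n:
            guess0 = epi_guess
        elif (epi_guess.size - 18) % 17 == 0 and stepper.problem.nc >= 1:
            # map across differing cell-type counts: replicate the first
            # cell block, carry over interspace and luminal potential
            cell = epi_guess[:17]
            tail = epi_guess[-18:]
            guess0 = np.concatenate(
                [np.tile(cell, stepper.problem.nc), tail]
            )
    try:
        x_epi, st0 = stepper.problem.solve(lum0, bath0, guess=guess0, s_torq=s0)
    except EpithelialConvergenceError as err:
        raise SegmentConvergenceError(geometry.id, 0.0, err) from err
    VL[0] = st0.lumen.V
    ST[0] = s0
    z = np.concatenate([x_epi, np.log(conc0), [np.log(inlet_yv)], [inlet_P]])

    prev = stepper._pack_prev(yv[0], yg[0], Ps[0])
    prev2 = None
    for j in range(1, N + 1):
        z, subdivided = stepper.step(z, xs[j], dx, prev, prev2)
        cL, yvj, Pj, VLj = stepper.state_at(z)
        CONC[j] = cL
        yv[j] = yvj
        yg[j] = (GROUP_MATRIX @ cL) * yvj
        Ps[j] = Pj
        VL[j] = VLj
        _, ST[j] = stepper.torque_scale_at(yvj / geometry.omega(xs[j]), Pj)
        prev2 = None if subdivided else prev
        prev = stepper._pack_prev(yv[j], yg[j], Ps[j])

    result = SegmentResult(
        geometry=geometry,
        x=xs,
        yv=yv,
        yg=yg,
        P=Ps,
        V_lumen=VL,
        conc=CONC,
        s_torq=ST,
        inlet_species=CONC[0] * yv[0],
        outlet_species=CONC[N] * yv[N],
    )
    result.final_epithelium = z[: stepper.problem.n].copy()
    result.n_salvaged = stepper.n_salvaged
    return result


# ---------------------------------------------------------------------------
# whole kidney
# ---------------------------------------------------------------------------


class KidneyConvergenceError(RuntimeError):
    def __init__(self, label: str, err: Exception):
        super().__init__(f"nephron class {label} failed: {err}")
        self.label = label


@dataclass
class KidneySolution:
    """Solved nephron classes plus the shared collecting-duct chain."""

    classes: dict[str, list[SegmentResult]]
    class_weights: dict[str, float]
    collecting_duct: list[SegmentResult]
    nephron_count: float
    filtered_groups: np.ndarray  # umol/s per kidney
    filtered_volume: float  # cm^3/s per kidney
    filtered_species: np.ndarray

    def warm_starts(self) -> dict[str, np.ndarray]:
        """Per-segment converged epithelial vectors, for re-solves."""
        out: dict[str, np.ndarray] = {}
        for label, results in self.classes.items():
            for r in results:
                if r.final_epithelium is not None:
                    out[f"{label}:{r.geometry.id}"] = r.final_epithelium
        for r in self.collecting_duct:
            if r.final_epithelium is not None:
                out[f"CD:{r.geometry.id}"] = r.final_epithelium
        return out

    @property
    def urine_flow(self) -> float:
        """Urine flow per kidney, cm^3/s."""
        return self.collecting_duct[-1].yv[-1] * self.nephron_count

    @property
    def urine_groups(self) -> np.ndarray:
        return self.collecting_duct[-1].yg[-1] * self.nephron_count

    @property
    def urine_species(self) -> np.ndarray:
        return self.collecting_duct[-1].outlet_species * self.nephron_count

    def segment_results(self, seg_id: str) -> dict[str, SegmentResult]:
        out = {}
        for label, results in self.classes.items():
            for r in results:
                if r.geometry.id == seg_id:
                    out[label] = r
        for r in self.collecting_duct:
            if r.geometry.id == seg_id:
                out["CD"] = r
        return out

    def kidney_reabsorption(self, seg_id: str) -> tuple[float, np.ndarray]:
        """Net (volume, group) reabsorption of a segment, per kidney."""
        vol = 0.0
        grp = np.zeros(N_GROUPS)
        for label, results in self.classes.items():
            w = self.class_weights[label] * self.nephron_count
            for r in results:
                if r.geometry.id == seg_id:
                    vol += w * r.net_volume_reabsorption
                    grp += w * r.net_reabsorption
        for r in self.collecting_duct:
            if r.geometry.id == seg_id:
                vol += self.nephron_count * r.net_volume_reabsorption
                grp += self.nephron_count * r.net_reabsorption
        return vol, grp


def assemble_kidney(
    model, sngfr_scale: float = 1.0,
    warm: dict[str, np.ndarray] | None = None,
) -> KidneySolution:
    """Solve all six nephron classes and the coalescing collecting duct.

    ``model`` is a :class:`~nephroflux.parameters.ModelParameterSet`;
    ``sngfr_scale`` uniformly rescales every class SNGFR (used by the
    saline-load protocol).  The cortical collecting duct inlet is the
    population-weighted sum of the connecting-tubule outflows; urine is
    the inner-medullary collecting duct outflow scaled by nephron count.
    ``warm`` optionally carries per-segment epithelial solutions from a
    previous (nearby) solve to accelerate re-solves; segment inlets also
    reuse the solution of the same segment in the previously solved class.
    """
    warm = dict(warm or {})
    from .parameters import compile_class_segments, compile_cd_segments

    interstitium = model.interstitial_profile()
    plasma = model.plasma_species()
    plasma_groups = GROUP_MATRIX @ plasma

    class_results: dict[str, list[SegmentResult]] = {}
    weights: dict[str, float] = {}
    filtered_vol = 0.0
    filtered_groups = np.zeros(N_GROUPS)
    filtered_species = np.zeros(15)
    ccd_yv = 0.0
    ccd_yg = np.zeros(N_GROUPS)
    ccd_P = 0.0

    for cls in model.nephron_classes():
        weights[cls.label] = cls.weight
        q0 = cls.sngfr * sngfr_scale
        yv = q0
        yg = plasma_groups * q0
        P = model.inlet_pressure
        filtered_vol += cls.weight * model.nephron_count * q0
        filtered_groups += cls.weight * model.nephron_count * yg
        filtered_species += cls.weight * model.nephron_count * plasma * q0
        results = []
        epi_guess = None
        try:
            for geom, spec, torque in compile_class_segments(model, cls):
                guess = warm.get(f"{cls.label}:{geom.id}")
                if guess is None:
                    guess = warm.get(f"_prev:{geom.id}", epi_guess)
                res = solve_segment(
                    geom, spec, yv, yg, P, interstitium,
                    torque=torque, viscosity=model.viscosity,
                    options=model.solver_options, epi_guess=guess,
                )
                results.append(res)
                epi_guess = res.final_epithelium
                warm[f"_prev:{geom.id}"] = res.final_epithelium
                yv, yg, P = res.yv[-1], res.yg[-1], res.P[-1]
        except SegmentConvergenceError as err:
            raise KidneyConvergenceError(cls.label, err) from err
        class_results[cls.label] = results
        ccd_yv += cls.weight * yv
        ccd_yg += cls.weight * yg
        ccd_P += cls.weight * yv * P

    ccd_P /= ccd_yv  # flow-weighted inlet pressure
    cd_results: list[SegmentResult] = []
    yv, yg, P = ccd_yv, ccd_yg, ccd_P
    epi_guess = None
    try:
        for geom, spec, torque in compile_cd_segments(model):
            guess = warm.get(f"CD:{geom.id}", epi_guess)
            res = solve_segment(
                geom, spec, yv, yg, P, interstitium,
                torque=torque, viscosity=model.viscosity,
                options=model.solver_options, epi_guess=guess,
            )
            cd_results.append(res)
            epi_guess = res.final_epithelium
            yv, yg, P = res.yv[-1], res.yg[-1], res.P[-1]
    except SegmentConvergenceError as err:
        raise KidneyConvergenceError("CD", err) from err

    return KidneySolution(
        classes=class_results,
        class_weights=weights,
        collecting_duct=cd_results,
        nephron_count=model.nephron_count,
        filtered_groups=filtered_groups,
        filtered_volume=filtered_vol,
        filtered_species=filtered_species,
    )
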
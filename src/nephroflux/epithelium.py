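"""Steady-state solver for one epithelial cross-section.

A cross-section couples a luminal fluid column (composition and pressure
given), one or two epithelial cell types, a shared paracellular (lateral
interspace) compartment and the peritubular bath.  Unknowns are the
interior concentrations and potentials, the interspace pressure and the
luminal potential; each cell's volume closure (an osmoregulated neutral
osmolyte pool, linear in every water flux) is eliminated analytically so
cell volume conservation holds identically.  Equations are:

* volume conservation in the interspace,
* conservation of each reaction-conserved solute group,
* mass-action relations for the buffer pairs (CO2 hydration finite-rate
  in cells, at equilibrium in the interspace),
* electroneutrality of each interior compartment (closing the proton
  balance),
* zero net ionic current into each interior compartment and out of the
  lumen (open-circuit condition fixing the potentials).

The system is solved by a damped quasi-Newton iteration on
log-concentration variables with a finite-difference Jacobian that is
reused across nearby solves (warm starts along a tubule), plus an
activity-continuation fallback for cold starts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla

from .constants import CONSTANTS, PhysicalConstants
from .fluxes import (
    MembraneSpec,
    atpase_flux,
    coupled_flux,
)
from .solutes import (
    CO2,
    GROUP_MATRIX,
    GROUP_NAMES,
    H,
    H2CO3,
    HCO3,
    KD_DEHYDRATION,
    KH_HYDRATION,
    KHYD_RATIO,
    N_SOLUTES,
    VALENCE,
    BUFFER_PAIRS,
)

_IDX = {g: i for i, g in enumerate(GROUP_NAMES)}
_G_CO2 = _IDX["CO2"]
_G_BIC = _IDX["bicarbonate"]
# groups with plain (reaction-free) balances
_PLAIN_GROUPS = tuple(i for g, i in _IDX.items() if g not in ("CO2", "bicarbonate"))
_PAIR_PHOS, _PAIR_AMM, _PAIR_FORM, _PAIR_CARB = BUFFER_PAIRS
_CHARGE_SCALE = 150.0


@dataclass
class CompartmentState:
    """Concentrations (mM), potential (mV) and pressure (mmHg) at one spot."""

    conc: np.ndarray
    V: float
    P: float
    id: str = "?"

    def __post_init__(self) -> None:
        self.conc = np.asarray(self.conc, dtype=float)
        if self.conc.shape != (N_SOLUTES,):
            raise ValueError("compartment needs a 15-solute concentration vector")
        if np.any(self.conc <= 0):
            raise ValueError(f"non-positive concentration in compartment {self.id}")


@dataclass
class CellSpec:
    """One epithelial cell type with its three membranes.

    Membrane areas are cm^2 per cm tubule and must already include the
    cell type's share of the epithelium.  ``imp_charge`` (signed, mM) is
    the fixed impermeant charge; ``imp_osm`` is the reference neutral
    osmolyte pool (the solved pool is computed from the water balance).
    ``ca_factor`` multiplies the CO2 hydration/dehydration rates
    (carbonic anhydrase catalysis).
    """

    name: str
    vol_ref: float
    imp_charge: float
    imp_osm: float
    apical: MembraneSpec
    lateral: MembraneSpec
    basal: MembraneSpec
    ca_factor: float = 1.0


@dataclass
class EpitheliumSpec:
    """All membranes of one cross-section."""

    cells: list[CellSpec]
    tight_junction: MembraneSpec
    basement: MembraneSpec
    lumen_ca_factor: float = 1.0


@dataclass
class SolverOptions:
    tol: float = 1e-12
    #: residual norm still considered converged when progress stalls at the
    #: finite-difference noise floor
    accept_tol: float = 1e-5
    max_iter: int = 100
    v_cell_init: float = -60.0
    v_para_init: float = 0.0
    v_lumen_init: float = 0.0
    clamp_potentials: bool = False
    continuation: tuple[float, ...] = (0.05, 0.2, 0.5, 1.0)


class EpithelialConvergenceError(RuntimeError):
    """Raised when the cross-section Newton iteration fails.

    Carries the last residual norm and the index/name of the worst
    equation for diagnosis.
    """

    def __init__(self, message: str, residual_norm: float, worst_index: int):
        super().__init__(
            f"{message} (|r|_inf = {residual_norm:.3e}, worst equation {worst_index})"
        )
        self.residual_norm = residual_norm
        self.worst_index = worst_index


class NewtonCache:
    """Jacobian factorisation reused across warm-started solves."""

    def __init__(self) -> None:
        self.lu = None
        self.jac = None
        self.central = False  # escalate to central differences on stalls

    def clear(self) -> None:
        self.lu = None
        self.jac = None


def damped_newton(
    fun,
    x0: np.ndarray,
    max_step: np.ndarray,
    options: SolverOptions,
    cache: NewtonCache,
) -> np.ndarray:
    """Damped quasi-Newton on a scaled residual, with lazy Jacobian reuse.

    ``fun(x)`` returns the scaled residual.  The finite-difference Jacobian
    is LU-factorised into ``cache`` and reused while the contraction stays
    good (warm starts along a tubule typically converge without a single
    refresh); damped steps or weak reductions trigger a refresh.  Steps are
    clipped per component by ``max_step``.
    """
    n = x0.size

    def jacobian(x: np.ndarray) -> np.ndarray:
        J = np.empty((n, n))
        F0 = None if cache.central else fun(x)
        for j in range(n):
            h = 1e-5 * max(1.0, abs(x[j]))
            xp = x.copy()
            xp[j] += h
            if cache.central:
                # second-order truncation keeps the polish floor near
                # machine precision on stubborn cross-sections
                xm = x.copy()
                xm[j] -= h
                J[:, j] = (fun(xp) - fun(xm)) / (2.0 * h)
            else:
                J[:, j] = (fun(xp) - F0) / h
        return J

    x = x0.copy()
    F = fun(x)
    best_inf = float(np.max(np.abs(F)))
    best_2 = float(np.linalg.norm(F))
    for _ in range(options.max_iter):
        if best_inf < options.tol:
            return x
        fresh = cache.lu is None
        if fresh:
            cache.jac = jacobian(x)
            try:
                cache.lu = sla.lu_factor(cache.jac)
            except Exception:
                raise EpithelialConvergenceError(
                    "singular Jacobian", best_inf, int(np.argmax(np.abs(F)))
                )
        dx_raw = -sla.lu_solve(cache.lu, F)
        ratio = np.max(np.abs(dx_raw) / max_step)
        candidates = [dx_raw]
        if ratio > 4.0:
            # runaway component (e.g. a depleting solute walking in log
            # space): try a per-component clip first so the rest of the
            # step survives, but keep the true (scaled) Newton direction
            # as fallback -- only the latter is a guaranteed descent
            # direction for the 2-norm merit
            candidates = [np.clip(dx_raw, -max_step, max_step), dx_raw / ratio]
        elif ratio > 1.0:
            candidates = [dx_raw / ratio]
        if fresh:
            # regularised direction as a last resort on ill-conditioned
            # Jacobians, where the LU solve can point uphill
            dx_ls = -np.linalg.lstsq(cache.jac, F, rcond=1e-10)[0]
            r2 = np.max(np.abs(dx_ls) / max_step)
            if r2 > 4.0:
                dx_ls = np.clip(dx_ls, -max_step, max_step)
            elif r2 > 1.0:
                dx_ls = dx_ls / r2
            candidates = candidates + [dx_ls]
        # line search on the 2-norm merit; convergence judged on max norm
        accepted = False
        prev_2 = best_2
        lam = 1.0
        for dx in candidates:
            lam = 1.0
            while lam >= 1.0 / 8192.0:
                xn = x + lam * dx
                with np.errstate(over="raise", invalid="raise"):
                    try:
                        Fn = fun(xn)
                    except (FloatingPointError, ValueError, ZeroDivisionError):
                        lam *= 0.5
                        continue
                n2 = float(np.linalg.norm(Fn))
                ninf = float(np.max(np.abs(Fn)))
                if n2 < best_2 * (1.0 - 1e-4 * lam) or ninf < options.tol:
                    x, F = xn, Fn
                    best_2, best_inf = n2, ninf
                    accepted = True
                    break
                lam *= 0.5
            if accepted:
                break
        if not accepted and fresh and not cache.central:
            # retry with an accurate central-difference Jacobian before
            # resorting to Levenberg-Marquardt
            cache.clear()
            cache.central = True
            continue
        if not accepted and fresh:
            # Levenberg-Marquardt fallback: damp the normal equations, which
            # bends the step toward steepest descent of the 2-norm merit and
            # restores guaranteed descent near singular Jacobians
            JtJ = cache.jac.T @ cache.jac
            g = cache.jac.T @ F
            diag = np.diag(JtJ).copy()
            diag[diag <= 0] = 1.0
            for alpha in (1e-4, 1e-2, 1.0, 1e2, 1e4):
                try:
                    dx = -np.linalg.solve(JtJ + alpha * np.diag(diag), g)
                except np.linalg.LinAlgError:
                    continue
                r = np.max(np.abs(dx) / max_step)
                if r > 1.0:
                    dx /= r
                lam = 1.0
                while lam >= 1.0 / 64.0:
                    xn = x + lam * dx
                    with np.errstate(over="raise", invalid="raise"):
                        try:
                            Fn = fun(xn)
                        except (FloatingPointError, ValueError):
                            lam *= 0.5
                            continue
                    n2 = float(np.linalg.norm(Fn))
                    if n2 < best_2 * (1.0 - 1e-6 * lam):
                        x, F = xn, Fn
                        best_2 = n2
                        best_inf = float(np.max(np.abs(Fn)))
                        accepted = True
                        break
                    lam *= 0.5
                if accepted:
                    break
            cache.clear()
            if not accepted:
                if best_inf < options.accept_tol:
                    return x
                raise EpithelialConvergenceError(
                    "line search stalled", best_inf, int(np.argmax(np.abs(F)))
                )
            continue
        if not accepted:
            cache.clear()  # stale Jacobian: refresh and retry
            continue
        # refresh when the contraction is clearly poor: heavily damped
        # steps and weak reductions signal that the local linear model has
        # drifted (mildly damped steps are tolerated to keep the warm-march
        # Jacobian reuse effective)
        if lam < 0.25 or best_2 > 0.6 * prev_2:
            cache.clear()
    if best_inf < options.accept_tol:
        return x
    raise EpithelialConvergenceError(
        "max iterations exceeded", best_inf, int(np.argmax(np.abs(F)))
    )


@dataclass
class EpithelialState:
    """A converged cross-section: compartments plus per-membrane fluxes.

    ``fluxes`` maps membrane labels (``"LC:<cell>"``, ``"CP:<cell>"``,
    ``"CB:<cell>"``, ``"LP"``, ``"PB"``) to dicts with ``"Jv"`` (cm^3/s per
    cm tubule), ``"Jk"`` (umol/s per cm, 15-vector) and a per-mechanism
    breakdown of ``"Jk"``.
    """

    lumen: CompartmentState
    cells: list[CompartmentState]
    para: CompartmentState
    bath: CompartmentState
    cell_volumes: list[float]
    fluxes: dict[str, dict]
    s_torq: float
    residual_norm: float

    @property
    def lumen_volume_flux(self) -> float:
        """Total volume flux out of the lumen, cm^3/s per cm tubule."""
        out = self.fluxes["LP"]["Jv"]
        for key, rec in self.fluxes.items():
            if key.startswith("LC:"):
                out += rec["Jv"]
        return out

    @property
    def lumen_solute_flux(self) -> np.ndarray:
        """Total solute flux out of the lumen, umol/s per cm tubule."""
        out = self.fluxes["LP"]["Jk"].copy()
        for key, rec in self.fluxes.items():
            if key.startswith("LC:"):
                out += rec["Jk"]
        return out

    def dump(self) -> str:
        """Human-readable snapshot of the cross-section (for regressions)."""
        from .solutes import SOLUTES

        lines = [f"# cross-section dump (S_torq = {self.s_torq:.6f})"]
        comps = [("lumen", self.lumen)] + [
            (f"cell:{i}", c) for i, c in enumerate(self.cells)
        ] + [("para", self.para), ("bath", self.bath)]
        header = "solute\t" + "\t".join(name for name, _ in comps)
        lines.append(f"potential_mV\t" + "\t".join(f"{c.V:.6f}" for _, c in comps))
        lines.append(f"pressure_mmHg\t" + "\t".join(f"{c.P:.6f}" for _, c in comps))
        lines.append(header)
        for k, s in enumerate(SOLUTES):
            lines.append(
                s + "\t" + "\t".join(f"{c.conc[k]:.8g}" for _, c in comps)
            )
        lines.append("# fluxes per membrane (Jv cm^3/s/cm; Jk umol/s/cm)")
        for key, rec in self.fluxes.items():
            lines.append(f"{key}\tJv\t{rec['Jv']:.8g}")
            for k, s in enumerate(SOLUTES):
                if rec["Jk"][k] != 0.0:
                    lines.append(f"{key}\t{s}\t{rec['Jk'][k]:.8g}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# problem assembly
# ---------------------------------------------------------------------------


def _membrane_transport(
    mem: MembraneSpec,
    c_a: np.ndarray,
    c_b: np.ndarray,
    V_a: float,
    V_b: float,
    P_a: float,
    P_b: float,
    imp_a: float,
    imp_b: float,
    act_scale: float,
    constants: PhysicalConstants,
    breakdown: bool = False,
):
    """Volume and solute transport across one membrane, per cm tubule."""
    if mem.area == 0.0:
        zero = np.zeros(N_SOLUTES)
        if breakdown:
            return 0.0, zero, {m: zero.copy() for m in
                               ("convective", "electrodiffusive", "coupled", "ATP-driven")}
        return 0.0, zero, None
    dP = P_a - P_b
    osm = float(mem.sigma_k @ (c_a - c_b)) + imp_a - imp_b
    jv_area = mem.Lp * (dP - constants.RT_osm * osm)
    if act_scale == 1.0:
        h = mem.effective_perm  # cached on the spec
    else:
        h = mem.perm.copy()
        for t in mem.transporters:
            if t.kind == "channel":
                for k, s in t.stoich.items():
                    h[k] += act_scale * t.activity * abs(s)
    # log-mean concentration (streamlined: inputs are positive here)
    d = c_a - c_b
    tiny = np.abs(d) < 1e-9 * c_a
    cbar = np.where(tiny, c_a, d / np.log(np.where(tiny, 2.0, c_a / c_b)))
    conv = (1.0 - mem.sigma_k) * cbar * jv_area
    # GHK electrodiffusion with the series patch near zeta = 0
    zeta = VALENCE * (constants.F_RT * (V_a - V_b))
    small = np.abs(zeta) < 1e-4
    zs = np.where(small, 1.0, zeta)
    ed = np.where(
        small,
        d + zeta * (c_a + c_b) / 2.0 + zeta * zeta * d / 12.0,
        zs / (1.0 - np.exp(-zs)) * (c_a - c_b * np.exp(-zs)),
    )
    ed = h * ed
    coup = np.zeros(N_SOLUTES)
    pump = np.zeros(N_SOLUTES)
    for t in mem.transporters:
        if t.kind in ("cotransporter", "exchanger"):
            coup += act_scale * coupled_flux(t, c_a, c_b, V_a - V_b, constants)
        elif t.kind == "ATPase":
            pump += act_scale * atpase_flux(t, c_a, c_b)
    jk = mem.area * (conv + ed + coup + pump)
    rec = None
    if breakdown:
        rec = {
            "convective": mem.area * conv,
            "electrodiffusive": mem.area * ed,
            "coupled": mem.area * coup,
            "ATP-driven": mem.area * pump,
        }
    return mem.area * jv_area, jk, rec


def _group_capacity(mem: MembraneSpec, c_ref: np.ndarray) -> np.ndarray:
    """Per-group transport capacity of a membrane (umol/s/cm scale)."""
    cap_k = mem.effective_perm * np.maximum(c_ref, 1e-3)
    cap = GROUP_MATRIX @ cap_k
    for t in mem.transporters:
        if t.kind == "channel":
            continue
        for k, s in t.stoich.items():
            g = _solute_group(k)
            if g is not None and s != 0:
                cap[g] += t.activity * abs(s)
        for _, stoich in t.modes:
            for k, s in stoich.items():
                g = _solute_group(k)
                if g is not None and s != 0:
                    cap[g] += t.activity * abs(s)
    return mem.area * cap


def _solute_group(k: int) -> int | None:
    col = GROUP_MATRIX[:, k]
    nz = np.nonzero(col)[0]
    return int(nz[0]) if nz.size else None


def _chem_residuals_cell(c: np.ndarray) -> np.ndarray:
    """The four mass-action residuals (log form) for a cell compartment."""
    h_molar = c[H] * 1e-3
    return np.array([
        np.log(c[_PAIR_PHOS.base] * h_molar / (c[_PAIR_PHOS.acid] * _PAIR_PHOS.K)),
        np.log(c[_PAIR_AMM.base] * h_molar / (c[_PAIR_AMM.acid] * _PAIR_AMM.K)),
        np.log(c[_PAIR_FORM.base] * h_molar / (c[_PAIR_FORM.acid] * _PAIR_FORM.K)),
        np.log(c[_PAIR_CARB.base] * h_molar / (c[_PAIR_CARB.acid] * _PAIR_CARB.K)),
    ])


class EpitheliumProblem:
    """Compiled steady-state problem for one cross-section geometry.

    Instances cache residual scaling and the last Jacobian factorisation,
    so that repeated solves along a tubule (warm starts) cost only a
    handful of residual evaluations each.
    """

    def __init__(
        self,
        spec: EpitheliumSpec,
        options: SolverOptions | None = None,
        constants: PhysicalConstants = CONSTANTS,
    ):
        self.spec = spec
        self.options = options or SolverOptions()
        self.constants = constants
        self.nc = len(spec.cells)
        self.n = 17 * self.nc + 17 + 1
        self._cache = NewtonCache()
        self._scales: np.ndarray | None = None
        self._pins: dict | None = None
        # per-component trust region: log-concentrations move at most 2,
        # potentials 30 mV, interspace pressure 20 mmHg per Newton step
        step = np.full(self.n, 2.0)
        for i in range(self.nc):
            step[17 * i + 15] = 30.0
            # the osmolyte pool enters the volume balance linearly; allow
            # large moves (deep-medulla cells sit hundreds of mOsm above
            # a dilute lumen)
            step[17 * i + 16] = 400.0
        step[self._para_off + 15] = 30.0
        step[self._para_off + 16] = 20.0
        step[-1] = 30.0
        self._max_step = step

    # -- layout helpers ---------------------------------------------------
    def _cell_slice(self, i: int) -> slice:
        return slice(17 * i, 17 * (i + 1))

    @property
    def _para_off(self) -> int:
        return 17 * self.nc

    def initial_guess(self, bath: CompartmentState) -> np.ndarray:
        x = np.zeros(self.n)
        o = self.options
        for i in range(self.nc):
            s = self._cell_slice(i)
            x[s.start : s.start + 15] = np.log(bath.conc)
            x[s.start + 15] = o.v_cell_init
            x[s.start + 16] = self.spec.cells[i].imp_osm
        p = self._para_off
        x[p : p + 15] = np.log(bath.conc)
        x[p + 15] = o.v_para_init
        x[p + 16] = bath.P
        x[-1] = o.v_lumen_init
        return x

    # -- capacities / structural pinning ---------------------------------
    def _compute_structure(self, bath: CompartmentState) -> None:
        spec = self.spec
        pins = {"cells": [], "para": {}, "lumen_v": False}
        c_ref = bath.conc
        charged = np.abs(VALENCE) > 0
        for cell in spec.cells:
            mems = (cell.apical, cell.lateral, cell.basal)
            cap = sum(_group_capacity(m, c_ref) for m in mems)
            water = sum(m.area * m.Lp for m in mems)
            cur = 0.0
            for m in mems:
                cur += m.area * float(
                    (m.effective_perm * np.maximum(c_ref, 1e-3))[charged].sum()
                )
                for t in m.transporters:
                    if t.kind == "channel":
                        continue
                    cur += m.area * t.activity
            pins["cells"].append({
                "groups": cap <= 0.0,
                "water": water <= 0.0,
                "current": cur <= 0.0 or self.options.clamp_potentials,
                "no_ions": cur <= 0.0 or self.options.clamp_potentials,
                "carb_dead": cap[_G_CO2] <= 0.0 and cap[_G_BIC] <= 0.0,
            })
        mems = [spec.tight_junction, spec.basement] + [c.lateral for c in spec.cells]
        cap = sum(_group_capacity(m, c_ref) for m in mems)
        water = sum(m.area * m.Lp for m in mems)
        cur = 0.0
        for m in mems:
            cur += m.area * float(
                (m.effective_perm * np.maximum(c_ref, 1e-3))[charged].sum()
            )
            for t in m.transporters:
                if t.kind == "channel":
                    continue
                cur += m.area * t.activity
        pins["para"] = {
            "groups": cap <= 0.0,
            "water": water <= 0.0,
            "current": cur <= 0.0 or self.options.clamp_potentials,
            "no_ions": cur <= 0.0 or self.options.clamp_potentials,
            "carb_dead": cap[_G_CO2] <= 0.0 and cap[_G_BIC] <= 0.0,
        }
        lum_mems = [spec.tight_junction] + [c.apical for c in spec.cells]
        lcur = 0.0
        for m in lum_mems:
            lcur += m.area * float(
                (m.effective_perm * np.maximum(c_ref, 1e-3))[charged].sum()
            )
            for t in m.transporters:
                if t.kind == "channel":
                    continue
                lcur += m.area * t.activity
        pins["lumen_v"] = lcur <= 0.0 or self.options.clamp_potentials

        # residual scales
        scales = np.ones(self.n)
        floor = 1e-12
        for i, cell in enumerate(spec.cells):
            mems = (cell.apical, cell.lateral, cell.basal)
            cap = sum(_group_capacity(m, c_ref) for m in mems) + floor
            rx = cell.vol_ref * KD_DEHYDRATION * cell.ca_factor * max(
                KHYD_RATIO * c_ref[CO2], 1e-6
            )
            s = self._cell_slice(i).start
            gsc = cap.copy()
            gsc[_G_CO2] += rx
            gsc[_G_BIC] += rx
            pin = pins["cells"][i]
            gsc[pin["groups"]] = 1.0  # pinned balances are log residuals
            if pin["carb_dead"]:
                gsc[_G_CO2] = gsc[_G_BIC] = 1.0
            scales[s : s + 10] = gsc
            scales[s + 10 : s + 14] = 1.0  # chemistry (log) residuals
            scales[s + 14] = 1.0  # electroneutrality, already /150
            if pin["water"]:
                scales[s + 15] = 1.0
            else:
                scales[s + 15] = (
                    sum(m.area * m.Lp for m in mems)
                    * self.constants.RT_osm * 10.0
                )
            if pin["current"]:
                scales[s + 16] = 1.0
            else:
                scales[s + 16] = float(
                    cap[[_IDX["Na"], _IDX["K"], _IDX["Cl"]]].sum()
                ) + floor
        mems = [spec.tight_junction, spec.basement] + [c.lateral for c in spec.cells]
        cap = sum(_group_capacity(m, c_ref) for m in mems) + floor
        p = self._para_off
        gsc = cap.copy()
        gsc[pins["para"]["groups"]] = 1.0
        if pins["para"]["carb_dead"]:
            gsc[_G_CO2] = gsc[_G_BIC] = 1.0
        else:
            gsc[_G_BIC] = 1.0  # hydration-equilibrium (log) residual slot
            gsc[_G_CO2] = cap[_G_CO2] + cap[_G_BIC]
        scales[p : p + 10] = gsc
        scales[p + 10 : p + 15] = 1.0
        if pins["para"]["water"]:
            scales[p + 15] = 1.0
        else:
            scales[p + 15] = (
                sum(m.area * m.Lp for m in mems) * self.constants.RT_osm * 10.0
            )
        if pins["para"]["current"]:
            scales[p + 16] = 1.0
        else:
            scales[p + 16] = float(
                cap[[_IDX["Na"], _IDX["K"], _IDX["Cl"]]].sum()
            ) + floor
        if pins["lumen_v"]:
            scales[-1] = 1.0
        else:
            lcap = sum(
                _group_capacity(m, c_ref)
                for m in [spec.tight_junction] + [c.apical for c in spec.cells]
            ) + floor
            scales[-1] = float(lcap[[_IDX["Na"], _IDX["K"], _IDX["Cl"]]].sum()) + floor
        self._scales = scales
        self._pins = pins


    def _cell_imp_closure(
        self, cell, lumen_conc, c_cell, c_para, bath,
        P_lumen, P_para, s_torq,
    ) -> float:
        """Impermeant osmolality that balances the cell's water fluxes.

        All three membrane water fluxes are linear in the cell impermeant
        osmolality, so the volume-conservation closure can be eliminated
        exactly: this returns the unique osmolality at which water influx
        and efflux balance (the osmoregulated solute pool of the cell).
        """
        RT = self.constants.RT_osm
        a, l, b = cell.apical, cell.lateral, cell.basal
        denom = RT * (s_torq * a.area * a.Lp + l.area * l.Lp + b.area * b.Lp)
        jv0 = s_torq * a.area * a.Lp * (
            (P_lumen - bath.P) - RT * float(a.sigma_k @ (lumen_conc - c_cell))
        )
        jv0 -= l.area * l.Lp * (
            (bath.P - P_para) - RT * float(l.sigma_k @ (c_cell - c_para))
        )
        jv0 -= b.area * b.Lp * (
            -RT * float(b.sigma_k @ (c_cell - bath.conc))
        )
        return -jv0 / denom

    # -- residual ---------------------------------------------------------
    def residual(
        self,
        x: np.ndarray,
        lumen_conc: np.ndarray,
        P_lumen: float,
        bath: CompartmentState,
        s_torq: float = 1.0,
        act_scale: float = 1.0,
        scaled: bool = True,
        return_fluxes: bool = False,
    ):
        """Stacked steady-state residual vector at unknown vector ``x``.

        With ``return_fluxes`` the totals leaving the lumen (volume and the
        15 solutes, per cm tubule) are returned alongside the residual for
        use by the axial integrator.
        """
        spec = self.spec
        cons = self.constants
        nc = self.nc
        p = self._para_off
        F = np.zeros(self.n)

        c_para = np.exp(x[p : p + 15])
        V_para, P_para = x[p + 15], x[p + 16]
        V_lum = x[-1]
        net_para = np.zeros(N_SOLUTES)
        current_lumen = 0.0
        jv_lumen = 0.0
        jk_lumen = np.zeros(N_SOLUTES)

        for i, cell in enumerate(spec.cells):
            s = self._cell_slice(i).start
            c_cell = np.exp(x[s : s + 15])
            V_cell = x[s + 15]
            P_cell = bath.P
            vol = cell.vol_ref
            pin = self._pins["cells"][i]
            # the osmoregulated impermeant pool balances the water fluxes;
            # it is eliminated analytically (linear), and the unknown slot
            # just records it
            if pin["water"]:
                imp_osm_cell = x[s + 16] + abs(cell.imp_charge)
            else:
                imp_osm_cell = self._cell_imp_closure(
                    cell, lumen_conc, c_cell, c_para, bath,
                    P_lumen, P_para, s_torq,
                )
            # membranes: LC (lumen->cell), CP (cell->para), CB (cell->bath)
            jv_lc, jk_lc, _ = _membrane_transport(
                cell.apical, lumen_conc, c_cell, V_lum, V_cell, P_lumen, P_cell,
                0.0, imp_osm_cell, act_scale, cons,
            )
            jv_lc *= s_torq
            jk_lc = jk_lc * s_torq
            jv_cp, jk_cp, _ = _membrane_transport(
                cell.lateral, c_cell, c_para, V_cell, V_para, P_cell, P_para,
                imp_osm_cell, 0.0, act_scale, cons,
            )
            jv_cb, jk_cb, _ = _membrane_transport(
                cell.basal, c_cell, bath.conc, V_cell, bath.V, P_cell, bath.P,
                imp_osm_cell, 0.0, act_scale, cons,
            )
            net = jk_lc - jk_cp - jk_cb  # umol/s per cm, into the cell
            net_para += jk_cp
            current_lumen += float(VALENCE @ jk_lc)
            jv_lumen += jv_lc
            jk_lumen += jk_lc

            gnet = GROUP_MATRIX @ net
            # plain group balances
            for g in _PLAIN_GROUPS:
                if pin["groups"][g]:
                    k0 = _GROUP_PIN_SOLUTE[g]
                    F[s + g] = x[s + k0] - np.log(bath.conc[k0])
                else:
                    F[s + g] = gnet[g]
            # CO2 / bicarbonate with finite-rate hydration
            rate = (
                vol
                * cell.ca_factor
                * (KH_HYDRATION * c_cell[CO2] - KD_DEHYDRATION * c_cell[H2CO3])
            )
            if pin["carb_dead"]:
                F[s + _G_CO2] = x[s + CO2] - np.log(max(bath.conc[CO2], 1e-30))
                F[s + _G_BIC] = (
                    np.log(c_cell[HCO3] + c_cell[H2CO3])
                    - np.log(bath.conc[HCO3] + bath.conc[H2CO3])
                )
            else:
                F[s + _G_CO2] = gnet[_G_CO2] - rate
                F[s + _G_BIC] = gnet[_G_BIC] + rate
            F[s + 10 : s + 14] = _chem_residuals_cell(c_cell)
            if pin["no_ions"]:
                # no charged pathway: electroneutrality cannot bind; pin pH
                F[s + 14] = x[s + H] - np.log(bath.conc[H])
            else:
                F[s + 14] = (
                    float(VALENCE @ c_cell) + cell.imp_charge
                ) / _CHARGE_SCALE
            # volume balance holds identically through the eliminated
            # osmolyte pool; the spare slot is pinned to the configured
            # reference (the actual pool is reported on the solved state)
            F[s + 15] = (x[s + 16] - cell.imp_osm) / 10.0
            if pin["current"]:
                F[s + 16] = V_cell - self.options.v_cell_init
            else:
                F[s + 16] = float(VALENCE @ net)

        # paracellular compartment
        jv_lp, jk_lp, _ = _membrane_transport(
            spec.tight_junction, lumen_conc, c_para, V_lum, V_para, P_lumen, P_para,
            0.0, 0.0, act_scale, cons,
        )
        jv_lp *= s_torq
        jk_lp = jk_lp * s_torq
        jv_pb, jk_pb, _ = _membrane_transport(
            spec.basement, c_para, bath.conc, V_para, bath.V, P_para, bath.P,
            0.0, 0.0, act_scale, cons,
        )
        current_lumen += float(VALENCE @ jk_lp)
        jv_lumen += jv_lp
        jk_lumen += jk_lp
        # recompute jv into para from cells for volume balance
        jv_para_in = jv_lp - jv_pb
        jk_para_net = jk_lp + net_para - jk_pb
        for i, cell in enumerate(spec.cells):
            s = self._cell_slice(i).start
            c_cell = np.exp(x[s : s + 15])
            if self._pins["cells"][i]["water"]:
                imp_osm_cell = x[s + 16] + abs(cell.imp_charge)
            else:
                imp_osm_cell = self._cell_imp_closure(
                    cell, lumen_conc, c_cell, c_para, bath,
                    P_lumen, P_para, s_torq,
                )
            jv_cp, _, _ = _membrane_transport(
                cell.lateral, c_cell, c_para, x[s + 15], V_para, bath.P, P_para,
                imp_osm_cell, 0.0, act_scale, cons,
            )
            jv_para_in += jv_cp

        pinp = self._pins["para"]
        gnet = GROUP_MATRIX @ jk_para_net
        for g in _PLAIN_GROUPS:
            if pinp["groups"][g]:
                k0 = _GROUP_PIN_SOLUTE[g]
                F[p + g] = x[p + k0] - np.log(bath.conc[k0])
            else:
                F[p + g] = gnet[g]
        # interspace carbonate at full equilibrium: combined balance + hydration
        if pinp["carb_dead"]:
            F[p + _G_CO2] = x[p + CO2] - np.log(max(bath.conc[CO2], 1e-30))
            F[p + _G_BIC] = (
                np.log(c_para[HCO3] + c_para[H2CO3])
                - np.log(bath.conc[HCO3] + bath.conc[H2CO3])
            )
        else:
            F[p + _G_CO2] = gnet[_G_CO2] + gnet[_G_BIC]  # total carbonate
            F[p + _G_BIC] = np.log(c_para[H2CO3] / (KHYD_RATIO * c_para[CO2]))
        F[p + 10 : p + 14] = _chem_residuals_cell(c_para)
        if pinp["no_ions"]:
            F[p + 14] = x[p + H] - np.log(bath.conc[H])
        else:
            F[p + 14] = float(VALENCE @ c_para) / _CHARGE_SCALE
        if pinp["water"]:
            F[p + 15] = (P_para - bath.P) / 10.0
        else:
            F[p + 15] = jv_para_in
        if pinp["current"]:
            F[p + 16] = V_para - self.options.v_para_init
        else:
            F[p + 16] = float(VALENCE @ jk_para_net)

        if self._pins["lumen_v"]:
            F[-1] = V_lum - self.options.v_lumen_init
        else:
            F[-1] = current_lumen

        if scaled:
            F = F / self._scales
        if return_fluxes:
            return F, jv_lumen, jk_lumen
        return F

    # -- solver -----------------------------------------------------------
    def solve(
        self,
        lumen: CompartmentState,
        bath: CompartmentState,
        guess: np.ndarray | None = None,
        s_torq: float = 1.0,
    ) -> tuple[np.ndarray, "EpithelialState"]:
        """Solve the cross-section; returns (unknown vector, state)."""
        self._compute_structure(bath)
        args0 = (lumen.conc, lumen.P, bath, s_torq)
        x0 = guess.copy() if guess is not None else self.initial_guess(bath)
        try:
            x = self._newton(x0, args0 + (1.0,))
        except EpithelialConvergenceError:
            x = None
        if x is None:
            try:
                x = self._activity_continuation(lumen.conc, lumen.P, bath, s_torq)
            except EpithelialConvergenceError:
                x = None
        if x is None:
            # last resort: solve the symmetric problem (lumen = bath, an
            # easy fixed point) and morph the luminal composition toward
            # the actual one in adaptively bisected stages
            x = self._activity_continuation(bath.conc, bath.P, bath, s_torq)
            log_tgt = np.log(lumen.conc)
            log_src = np.log(bath.conc)
            lam_done = 0.0
            targets = [0.25, 0.5, 0.75, 1.0]
            while targets:
                lam = targets[0]
                conc = np.exp((1.0 - lam) * log_src + lam * log_tgt)
                P_mix = (1.0 - lam) * bath.P + lam * lumen.P
                try:
                    x = self._newton(x, (conc, P_mix, bath, s_torq, 1.0))
                    lam_done = lam
                    targets.pop(0)
                except EpithelialConvergenceError as err:
                    if lam - lam_done < 1e-3:
                        raise err
                    targets.insert(0, 0.5 * (lam + lam_done))
        state = self._build_state(x, lumen, bath, s_torq)
        return x, state

    def _activity_continuation(self, lumen_conc, P_lumen, bath, s_torq):
        """Ramp transporter activities up from near-passive, bisecting
        the ramp adaptively where a stage fails."""
        args0 = (lumen_conc, P_lumen, bath, s_torq)
        x = self.initial_guess(bath)
        lam_done = 0.0
        targets = sorted(set(self.options.continuation) | {1.0})
        while targets:
            lam = targets[0]
            try:
                x = self._newton(x, args0 + (lam,))
                lam_done = lam
                targets.pop(0)
            except EpithelialConvergenceError as err:
                if lam - lam_done < 1e-3:
                    raise err
                targets.insert(0, 0.5 * (lam + lam_done))
        return x

    def _newton(self, x0: np.ndarray, args) -> np.ndarray:
        return damped_newton(
            lambda x: self.residual(x, *args),
            x0,
            self._max_step,
            self.options,
            self._cache,
        )

    # -- state assembly ---------------------------------------------------
    def _build_state(
        self, x: np.ndarray, lumen: CompartmentState, bath: CompartmentState,
        s_torq: float,
    ) -> EpithelialState:
        spec = self.spec
        cons = self.constants
        p = self._para_off
        c_para = np.exp(x[p : p + 15])
        V_para, P_para = x[p + 15], x[p + 16]
        V_lum = x[-1]
        fluxes: dict[str, dict] = {}
        cells = []
        vols = []
        for i, cell in enumerate(spec.cells):
            s = self._cell_slice(i).start
            c_cell = np.exp(x[s : s + 15])
            V_cell = x[s + 15]
            P_cell = bath.P
            vol = cell.vol_ref
            if self._pins["cells"][i]["water"]:
                imp_osm_cell = x[s + 16] + abs(cell.imp_charge)
            else:
                imp_osm_cell = self._cell_imp_closure(
                    cell, lumen.conc, c_cell, c_para, bath,
                    lumen.P, P_para, s_torq,
                )
            jv, jk, br = _membrane_transport(
                cell.apical, lumen.conc, c_cell, V_lum, V_cell, lumen.P, P_cell,
                0.0, imp_osm_cell, 1.0, cons, breakdown=True,
            )
            fluxes[f"LC:{cell.name}"] = {
                "Jv": jv * s_torq,
                "Jk": jk * s_torq,
                **{m: v * s_torq for m, v in br.items()},
            }
            jv, jk, br = _membrane_transport(
                cell.lateral, c_cell, c_para, V_cell, V_para, P_cell, P_para,
                imp_osm_cell, 0.0, 1.0, cons, breakdown=True,
            )
            fluxes[f"CP:{cell.name}"] = {"Jv": jv, "Jk": jk, **br}
            jv, jk, br = _membrane_transport(
                cell.basal, c_cell, bath.conc, V_cell, bath.V, P_cell, bath.P,
                imp_osm_cell, 0.0, 1.0, cons, breakdown=True,
            )
            fluxes[f"CB:{cell.name}"] = {"Jv": jv, "Jk": jk, **br}
            cells.append(CompartmentState(c_cell, V_cell, P_cell, id="C"))
            vols.append(vol)
        jv, jk, br = _membrane_transport(
            spec.tight_junction, lumen.conc, c_para, V_lum, V_para, lumen.P, P_para,
            0.0, 0.0, 1.0, cons, breakdown=True,
        )
        fluxes["LP"] = {
            "Jv": jv * s_torq,
            "Jk": jk * s_torq,
            **{m: v * s_torq for m, v in br.items()},
        }
        jv, jk, br = _membrane_transport(
            spec.basement, c_para, bath.conc, V_para, bath.V, P_para, bath.P,
            0.0, 0.0, 1.0, cons, breakdown=True,
        )
        fluxes["PB"] = {"Jv": jv, "Jk": jk, **br}
        F = self.residual(x, lumen.conc, lumen.P, bath, s_torq, 1.0)
        return EpithelialState(
            lumen=CompartmentState(lumen.conc.copy(), V_lum, lumen.P, id="L"),
            cells=cells,
            para=CompartmentState(c_para, V_para, P_para, id="P"),
            bath=bath,
            cell_volumes=vols,
            fluxes=fluxes,
            s_torq=s_torq,
            residual_norm=float(np.max(np.abs(F))),
        )


#: which solute's log-concentration is pinned when a group has no pathway
_GROUP_PIN_SOLUTE = {}
for _g, _members in enumerate(GROUP_MATRIX):
    _idx = np.nonzero(_members)[0]
    _GROUP_PIN_SOLUTE[_g] = int(_idx[0])


def epithelial_residuals(
    problem: EpitheliumProblem,
    x: np.ndarray,
    lumen: CompartmentState,
    bath: CompartmentState,
    s_torq: float = 1.0,
) -> np.ndarray:
    """Scaled steady-state residual vector for a cross-section state."""
    problem._compute_structure(bath)
    return problem.residual(x, lumen.conc, lumen.P, bath, s_torq)


def solve_epithelium(
    spec: EpitheliumSpec,
    lumen: CompartmentState,
    bath: CompartmentState,
    guess: np.ndarray | None = None,
    s_torq: float = 1.0,
    options: SolverOptions | None = None,
) -> EpithelialState:
    """Convenience wrapper: compile, solve and return the converged state."""
    problem = EpitheliumProblem(spec, options)
    _, state = problem.solve(lumen, bath, guess=guess, s_torq=s_torq)
    return state
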
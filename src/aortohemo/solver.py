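"""Incompressible Navier–Stokes on the voxelized aorta.

Solves

    ρ (∂u/∂t + u·∇u) = −∇P + μ ∇²u,     ∇·u = 0

for blood treated as an incompressible Newtonian fluid (ρ = 1050 kg/m³,
μ = 0.004 Pa·s, zero body force) with rigid no-slip walls, a pulsatile inlet
velocity, and three-element Windkessel outlet pressures.

Discretization: uniform Cartesian staggered (MAC) grid over the voxel mask,
first-order upwind advection, explicit diffusion, and a pressure-projection
(fractional-step) update.  The pressure Poisson equation carries homogeneous
Neumann conditions at walls and the inlet and Dirichlet values (the Windkessel
pressures, mmHg → Pa) at outlet faces, so the system is well posed and the
post-projection velocity is discretely divergence-free in every fluid cell.
Solid walls are immersed: velocity components on faces touching a solid cell
are forced to zero each step (first-order stair-step no-slip).

Outlet coupling is explicit: the outward volume flux measured after the
projection feeds one backward-Euler Windkessel step, whose pressure is applied
as that outlet's uniform Dirichlet value on the next time step.  The identical
discrete map is exposed offline as :func:`aortohemo.windkessel.replay`, so a
run can be audited from its recorded flux traces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csc_matrix
from scipy.sparse.linalg import splu

from . import windkessel as wk
from .geometry import VoxelDomain
from .units import M3_S_TO_ML_S, MM_TO_M, MMHG_TO_PA

__all__ = [
    "FluidProperties",
    "SolverControls",
    "FlowField",
    "SimulationResult",
    "MacSolver",
    "courant_dt",
    "simulate_case",
]


@dataclass(frozen=True)
class FluidProperties:
    """Blood properties: density (kg/m³), dynamic viscosity (Pa·s)."""

    rho: float = 1050.0
    mu: float = 0.004
    body_force: float = 0.0  # N/m³, zero for aortic blood flow

    def __post_init__(self) -> None:
        if self.rho <= 0 or self.mu <= 0:
            raise ValueError("rho and mu must be > 0")

    @property
    def nu(self) -> float:
        return self.mu / self.rho


@dataclass
class SolverControls:
    """Time stepping and tolerance knobs.

    ``dt=None`` chooses the step from the CFL target and the waveform's peak
    velocity; a runtime CFL violation halves the step (down to ``dt_floor``).
    """

    dt: float | None = None
    cfl: float = 0.4
    n_cycles: int = 3
    div_tol: float = 1e-6          # s⁻¹, post-projection divergence bound
    periodicity_tol: float = 0.05  # cycle-to-cycle relative pressure change
    steady_tol: float = 1e-6       # per-step relative velocity change (steady runs)
    min_time: float = 0.0          # s, do not declare steady before this time
    dt_floor: float = 1e-7
    max_steps: int = 500_000
    waveform_resolution: int = 200  # adaptive dt cap: period / this
    distal_pressure_mmHg: float = 0.0  # uniform downstream reference added to all outlets
    inlet_profile: str = "plug"        # "plug" or "parabolic"


def courant_dt(domain: VoxelDomain, u_max: float, cfl: float = 0.4,
               props: FluidProperties = FluidProperties()) -> float:
    """Stable explicit time step: min(cfl·h/u_max, ρh²/(6μ))."""
    if u_max <= 0:
        raise ValueError("u_max must be > 0")
    h = domain.h * MM_TO_M
    return min(cfl * h / u_max, props.rho * h * h / (6.0 * props.mu))


@dataclass
class FlowField:
    """Staggered velocity (m/s) + cell pressure (Pa) snapshot."""

    u: np.ndarray
    v: np.ndarray
    w: np.ndarray
    p: np.ndarray
    t: float
    domain: VoxelDomain

    def cell_velocity(self) -> np.ndarray:
        """Velocity interpolated to cell centers, shape (*grid, 3)."""
        uc = 0.5 * (self.u[:-1] + self.u[1:])
        vc = 0.5 * (self.v[:, :-1] + self.v[:, 1:])
        wc = 0.5 * (self.w[:, :, :-1] + self.w[:, :, 1:])
        return np.stack([uc, vc, wc], axis=-1)

    def max_speed(self) -> float:
        return max(np.abs(self.u).max(), np.abs(self.v).max(), np.abs(self.w).max())


@dataclass
class SimulationResult:
    """Outcome of :func:`simulate_case`."""

    field: FlowField                       # final state
    peak_field: FlowField | None           # snapshot at peak systole, last cycle
    probes: pd.DataFrame                   # per-step traces
    outlet_traces: dict[str, pd.DataFrame]  # per outlet: t, Q_ml_s, P_mmHg
    periodicity: float
    warnings: list[str] = field(default_factory=list)
    max_divergence: float = 0.0
    dt: float = 0.0
    initial_states: dict[str, wk.WindkesselState] = field(default_factory=dict)


def _shift(a: np.ndarray, offset: int, axis: int) -> np.ndarray:
    """Shift with zero fill: result[i] = a[i + offset]."""
    out = np.zeros_like(a)
    src = [slice(None)] * a.ndim
    dst = [slice(None)] * a.ndim
    if offset > 0:
        src[axis] = slice(offset, None)
        dst[axis] = slice(None, -offset)
    elif offset < 0:
        src[axis] = slice(None, offset)
        dst[axis] = slice(-offset, None)
    else:
        return a.copy()
    out[tuple(dst)] = a[tuple(src)]
    return out


class MacSolver:
    """Projection solver bound to one voxel domain.

    Builds the face classification and the (constant) pressure Poisson
    operator once; :meth:`advance` performs a single fractional step.
    """

    def __init__(self, domain: VoxelDomain, props: FluidProperties = FluidProperties(),
                 controls: SolverControls | None = None):
        self.domain = domain
        self.props = props
        self.controls = controls or SolverControls()
        self.h = domain.h * MM_TO_M
        self.F = domain.fluid
        self.shape = domain.shape
        self._build_face_masks()
        self._build_poisson()
        self.u = np.zeros(self._face_shape(0))
        self.v = np.zeros(self._face_shape(1))
        self.w = np.zeros(self._face_shape(2))
        self.p = np.zeros(self.shape)
        self.t = 0.0

    def max_speed(self) -> float:
        return float(max(np.abs(self.u).max(), np.abs(self.v).max(),
                         np.abs(self.w).max()))

    # -- setup ------------------------------------------------------------

    def _face_shape(self, axis: int) -> tuple[int, ...]:
        s = list(self.shape)
        s[axis] += 1
        return tuple(s)

    def _build_face_masks(self) -> None:
        self.active = []
        for a in range(3):
            padw = [(0, 0)] * 3
            padw[a] = (1, 1)
            P = np.pad(self.F, padw, constant_values=False)
            sl_lo = [slice(None)] * 3
            sl_hi = [slice(None)] * 3
            sl_lo[a] = slice(0, -1)
            sl_hi[a] = slice(1, None)
            self.active.append(P[tuple(sl_lo)] & P[tuple(sl_hi)])

        # cap face masks; orientation sign = outward direction along the axis
        self.inlet_faces: tuple[int, np.ndarray] | None = None
        self.inlet_sign = 0
        self.outlets: list[dict] = []
        for cap in self.domain.caps:
            a, s = cap.axis, cap.side
            mask = np.zeros(self._face_shape(a), dtype=bool)
            fidx = cap.cells.copy()
            fidx[:, a] += 1 if s > 0 else 0
            mask[tuple(fidx.T)] = True
            if cap.label == "inlet":
                self.inlet_faces = (a, mask)
                self.inlet_sign = s
                self.inlet_cells = cap.cells
            else:
                self.outlets.append({
                    "label": cap.label, "axis": a, "side": s,
                    "mask": mask, "cells": cap.cells,
                })
        if self.inlet_faces is None:
            raise ValueError("domain has no inlet cap")

        # allowed (state-carrying) faces per axis: interior + caps
        self.allowed = []
        for a in range(3):
            m = self.active[a].copy()
            if self.inlet_faces[0] == a:
                m |= self.inlet_faces[1]
            for o in self.outlets:
                if o["axis"] == a:
                    m |= o["mask"]
            self.allowed.append(m)

        # inlet profile weights (unit mean; rescaled to the instantaneous flow)
        a, mask = self.inlet_faces
        cap = next(c for c in self.domain.geom.caps if c.label == "inlet")
        centers = self.domain.cell_centers(self.inlet_cells) * MM_TO_M
        c0 = cap.center * MM_TO_M
        r = np.linalg.norm(np.delete(centers - c0, a, axis=1), axis=1)
        R = cap.radius * MM_TO_M
        if self.controls.inlet_profile == "parabolic":
            prof = np.maximum(1.0 - (r / R) ** 2, 0.05)
        else:
            prof = np.ones_like(r)
        self._inlet_prof = prof / prof.mean()
        self._inlet_area = len(self.inlet_cells) * self.h ** 2

    def _build_poisson(self) -> None:
        F = self.F
        n = int(F.sum())
        idx = -np.ones(self.shape, dtype=np.int64)
        idx[F] = np.arange(n)
        self._cell_index = idx
        cells = np.argwhere(F)

        rows, cols, vals = [], [], []
        diag = np.zeros(n)
        # per-outlet Dirichlet rhs stencils: rhs += 2·P_o at these cells
        outlet_rhs = {o["label"]: np.zeros(n) for o in self.outlets}
        cap_face_sets = {}
        for o in self.outlets:
            keys = set(map(tuple, np.c_[o["cells"], np.full(len(o["cells"]), o["axis"]),
                                        np.full(len(o["cells"]), o["side"])]))
            cap_face_sets[o["label"]] = keys

        for a in range(3):
            for s in (-1, 1):
                nb = cells.copy()
                nb[:, a] += s
                inside = (nb[:, a] >= 0) & (nb[:, a] < self.shape[a])
                nb_fluid = np.zeros(len(cells), dtype=bool)
                nb_fluid[inside] = F[tuple(nb[inside].T)]
                ci = idx[tuple(cells.T)]
                nj = np.full(len(cells), -1, dtype=np.int64)
                nj[nb_fluid] = idx[tuple(nb[nb_fluid].T)]
                rows.append(ci[nb_fluid])
                cols.append(nj[nb_fluid])
                vals.append(-np.ones(nb_fluid.sum()))
                diag[ci[nb_fluid]] += 1.0
                # outlet faces → Dirichlet ghost (factor 2)
                not_fluid = ~nb_fluid
                if not_fluid.any():
                    for o in self.outlets:
                        if o["axis"] != a or o["side"] != s:
                            continue
                        keys = cap_face_sets[o["label"]]
                        hit = np.array([
                            (c[0], c[1], c[2], a, s) in keys
                            for c in cells[not_fluid]])
                        if hit.any():
                            which = ci[not_fluid][hit]
                            diag[which] += 2.0
                            np.add.at(outlet_rhs[o["label"]], which, 2.0)
                # everything else: Neumann → no entry

        rows.append(np.arange(n))
        cols.append(np.arange(n))
        vals.append(diag)
        A = csc_matrix((np.concatenate(vals),
                        (np.concatenate(rows), np.concatenate(cols))), shape=(n, n))
        self._lu = splu(A)
        self._outlet_rhs = outlet_rhs
        self._n_cells = n

    # -- boundary values ---------------------------------------------------

    def set_inlet_flow(self, Q_m3s: float) -> None:
        """Impose the inlet velocity profile for instantaneous flow Q (m³/s)."""
        a, mask = self.inlet_faces
        vel = (self.u, self.v, self.w)[a]
        vmean = Q_m3s / self._inlet_area
        fidx = self.inlet_cells.copy()
        fidx[:, a] += 1 if self.inlet_sign > 0 else 0
        vel[tuple(fidx.T)] = -self.inlet_sign * vmean * self._inlet_prof

    def outlet_flux(self, label: str) -> float:
        """Outward volume flux (m³/s) through a labeled outlet."""
        o = next(o for o in self.outlets if o["label"] == label)
        vel = (self.u, self.v, self.w)[o["axis"]]
        return float(o["side"] * vel[o["mask"]].sum() * self.h ** 2)

    def inlet_flux(self) -> float:
        a, mask = self.inlet_faces
        vel = (self.u, self.v, self.w)[a]
        return float(-self.inlet_sign * vel[mask].sum() * self.h ** 2)

    # -- single step -------------------------------------------------------

    def _advect_diffuse(self, comp: int) -> np.ndarray:
        """Predictor RHS (−u·∇q + ν∇²q) for one velocity component."""
        q = (self.u, self.v, self.w)[comp]
        h, nu = self.h, self.props.nu
        # upwind advection: advecting velocity per axis, interpolated to q faces
        adv = np.zeros_like(q)
        for a in range(3):
            if a == comp:
                va = q
            else:
                other = (self.u, self.v, self.w)[a]
                # average the 4 surrounding a-faces onto the comp-face
                padw = [(1, 1) if d == comp else (0, 0) for d in range(3)]
                op = np.pad(other, padw)
                lo = [slice(None)] * 3
                hi = [slice(None)] * 3
                lo[comp] = slice(0, -1)
                hi[comp] = slice(1, None)
                t1 = 0.5 * (op[tuple(lo)] + op[tuple(hi)])  # comp-dim: n_comp+1
                lo[comp] = hi[comp] = slice(None)
                lo[a] = slice(0, -1)
                hi[a] = slice(1, None)
                va = 0.5 * (t1[tuple(lo)] + t1[tuple(hi)])  # a-dim: n_a
            back = (q - _shift(q, -1, a)) / h
            fwd = (_shift(q, 1, a) - q) / h
            adv += va * np.where(va > 0, back, fwd)
        lap = np.zeros_like(q)
        for a in range(3):
            lap += _shift(q, 1, a) + _shift(q, -1, a)
        lap = (lap - 6.0 * q) / (h * h)
        return -adv + nu * lap

    def advance(self, dt: float, Q_in: float, outlet_P: dict[str, float]) -> float:
        """One fractional step.

        Q_in in m³/s, outlet_P in Pa.  Returns the max post-projection
        divergence (s⁻¹).  Raises on CFL violation beyond the dt floor
        (callers may catch and halve dt).
        """
        h, rho = self.h, self.props.rho
        umax = self.max_speed()
        if umax * dt / h > 1.0:
            raise FloatingPointError(
                f"CFL violation: u_max={umax:.3g} m/s, dt={dt:.3g} s, h={h:.3g} m")

        rhs_comp = [self._advect_diffuse(c) for c in range(3)]
        for c, arr in enumerate((self.u, self.v, self.w)):
            star = arr + dt * rhs_comp[c]
            star[~self.allowed[c]] = 0.0
            # outlet faces: zero-gradient extrapolation from one face inward;
            # the projection then sets their normal velocity from the pressure
            for o in self.outlets:
                if o["axis"] != c:
                    continue
                inner = _shift(star, -o["side"], c)
                star[o["mask"]] = inner[o["mask"]]
            if c == self.inlet_faces[0]:
                pass  # inlet set below on the updated array
            arr[...] = star
        self.set_inlet_flow(Q_in)

        # pressure Poisson:  M p = −h²·(ρ/dt)·div(u*) + Σ_o 2·P_o
        div = (np.diff(self.u, axis=0) + np.diff(self.v, axis=1)
               + np.diff(self.w, axis=2)) / h
        b = -(h * h) * (rho / dt) * div[self.F]
        for o in self.outlets:
            b += outlet_P[o["label"]] * self._outlet_rhs[o["label"]]
        p_flat = self._lu.solve(b)
        self.p.fill(0.0)
        self.p[self.F] = p_flat

        # velocity correction on interior faces
        coef = dt / (rho * h)
        Ppad = [np.pad(self.p, [(1, 1) if d == a else (0, 0) for d in range(3)])
                for a in range(3)]
        for a, arr in enumerate((self.u, self.v, self.w)):
            P = Ppad[a]
            sl_lo = [slice(None)] * 3
            sl_hi = [slice(None)] * 3
            sl_lo[a] = slice(0, -1)
            sl_hi[a] = slice(1, None)
            grad = P[tuple(sl_hi)] - P[tuple(sl_lo)]
            arr[self.active[a]] -= coef * grad[self.active[a]]
        # outlet faces: one-sided gradient against the Dirichlet face value
        for o in self.outlets:
            arr = (self.u, self.v, self.w)[o["axis"]]
            cell_p = self.p[tuple(o["cells"].T)]
            fidx = o["cells"].copy()
            fidx[:, o["axis"]] += 1 if o["side"] > 0 else 0
            # pressure difference over h/2 ghost distance, same 1/h scaling
            # as the interior faces (absorbed in coef)
            grad = o["side"] * 2.0 * (outlet_P[o["label"]] - cell_p)
            arr[tuple(fidx.T)] -= coef * grad

        self.t += dt
        div = (np.diff(self.u, axis=0) + np.diff(self.v, axis=1)
               + np.diff(self.w, axis=2)) / h
        return float(np.abs(div[self.F]).max())

    def snapshot(self) -> FlowField:
        return FlowField(self.u.copy(), self.v.copy(), self.w.copy(),
                         self.p.copy(), self.t, self.domain)


def _plane_probe_cells(solver: MacSolver):
    dom = solver.domain
    out = {}
    for loc in ("AscAo", "AI"):
        try:
            out[loc] = dom.plane_cells(loc)
        except (KeyError, ValueError):
            pass
    return out


def simulate_case(
    domain: VoxelDomain,
    inlet,
    outlets: dict[str, wk.WindkesselParams],
    props: FluidProperties = FluidProperties(),
    controls: SolverControls | None = None,
) -> SimulationResult:
    """Run a pulsatile (or steady) case with Windkessel-coupled outlets.

    ``inlet`` is a :class:`~aortohemo.synthetic_cohort.FlowWaveform` (ml/s,
    period in s).  Every labeled outlet of the domain must appear in
    ``outlets``.  Runs ``controls.n_cycles`` cardiac cycles (steady inflow
    runs until the per-step velocity change falls below ``steady_tol``) and
    records per-step probe traces; the returned ``peak_field`` is the snapshot
    at the instant of maximum inflow in the final cycle.
    """
    controls = controls or SolverControls()
    solver = MacSolver(domain, props, controls)
    labels = [o["label"] for o in solver.outlets]
    missing = [l for l in labels if l not in outlets]
    if missing:
        raise ValueError(f"missing Windkessel parameters for outlets: {missing}")

    T = inlet.period
    t_peak = inlet.peak_time
    steady = inlet.is_constant
    Q_mean_ml = inlet.mean_flow

    # per-outlet initialization at the cycle-mean steady split
    conductance = {l: 1.0 / outlets[l].total_resistance for l in labels}
    g_tot = sum(conductance.values())
    P0 = Q_mean_ml / g_tot  # common steady pressure, mmHg
    states = {l: wk.WindkesselState(P=P0, Q=P0 * conductance[l], t=0.0) for l in labels}
    initial_states = dict(states)
    P_distal = controls.distal_pressure_mmHg

    # adaptive stepping (dt tracked against the instantaneous CFL) unless an
    # explicit fixed dt was requested
    adaptive = controls.dt is None
    h_m = domain.h * MM_TO_M
    visc_cap = props.rho * h_m * h_m / (6.0 * props.mu)
    dt_cap = min(visc_cap, T / controls.waveform_resolution)
    if adaptive:
        u_guess = max(inlet.peak_flow * 1e-6 / solver._inlet_area, 1e-3) * 2.0
        dt = min(courant_dt(domain, u_guess, controls.cfl, props), dt_cap)
    else:
        dt = controls.dt

    probe_cells = _plane_probe_cells(solver)
    rec = {k: [] for k in ("t", "Q_in_ml_s", "p_inlet_mmHg", "psv_ascao_cm_s",
                           "p_ai_mmHg", "max_div")}
    outlet_rec = {l: {"t": [], "Q_ml_s": [], "P_mmHg": []} for l in labels}
    warn: list[str] = []

    inlet_adj = solver.inlet_cells
    t = 0.0
    max_div_seen = 0.0
    peak_field = None
    last_cycle_start = (controls.n_cycles - 1) * T
    cycle_pressures: list[float] = []
    cyc_minmax: list[tuple[float, float]] = []
    cur_min, cur_max = np.inf, -np.inf
    cycle_idx = 0
    n_step = 0
    prev_speed = None

    while True:
        if steady:
            if n_step >= controls.max_steps:
                warn.append("steady run hit max_steps before convergence")
                break
        elif t >= controls.n_cycles * T - 0.5 * dt:
            break

        if adaptive:
            umax = solver.max_speed()
            dt_cfl = (0.9 * controls.cfl * h_m / umax) if umax > 0 else dt_cap
            dt = float(np.clip(min(dt_cfl, dt_cap), controls.dt_floor, 1.25 * dt))
        Q_next_ml = float(inlet(t + dt))
        P_bc = {l: (states[l].P + P_distal) * MMHG_TO_PA for l in labels}
        try:
            mdiv = solver.advance(dt, Q_next_ml * 1e-6, P_bc)
        except FloatingPointError as e:
            dt *= 0.5
            if dt < controls.dt_floor:
                raise RuntimeError(f"time step collapsed below floor: {e}") from e
            warnings.warn(f"halving dt to {dt:.3g} s after {e}", stacklevel=2)
            continue
        t = solver.t
        n_step += 1
        max_div_seen = max(max_div_seen, mdiv)

        # windkessel update from the measured outlet fluxes (explicit coupling)
        for l in labels:
            Q_out_ml = solver.outlet_flux(l) * M3_S_TO_ML_S
            states[l] = wk.step(outlets[l], states[l], Q_out_ml, dt)
            outlet_rec[l]["t"].append(t)
            outlet_rec[l]["Q_ml_s"].append(Q_out_ml)
            outlet_rec[l]["P_mmHg"].append(states[l].P)

        p_inlet = float(solver.p[tuple(inlet_adj.T)].mean()) / MMHG_TO_PA
        rec["t"].append(t)
        rec["Q_in_ml_s"].append(Q_next_ml)
        rec["p_inlet_mmHg"].append(p_inlet)
        rec["max_div"].append(mdiv)
        if "AscAo" in probe_cells:
            ii, jj, kk = probe_cells["AscAo"].T
            uc = 0.5 * (solver.u[ii, jj, kk] + solver.u[ii + 1, jj, kk])
            vc = 0.5 * (solver.v[ii, jj, kk] + solver.v[ii, jj + 1, kk])
            wc = 0.5 * (solver.w[ii, jj, kk] + solver.w[ii, jj, kk + 1])
            speed = np.sqrt(uc ** 2 + vc ** 2 + wc ** 2)
            rec["psv_ascao_cm_s"].append(float(speed.max()) * 100.0)
        else:
            rec["psv_ascao_cm_s"].append(np.nan)
        if "AI" in probe_cells:
            cells = probe_cells["AI"]
            rec["p_ai_mmHg"].append(float(solver.p[tuple(cells.T)].mean()) / MMHG_TO_PA)
        else:
            rec["p_ai_mmHg"].append(np.nan)

        # periodicity bookkeeping on the first outlet pressure
        Pnow = states[labels[0]].P
        cur_min, cur_max = min(cur_min, Pnow), max(cur_max, Pnow)
        if not steady and t >= (cycle_idx + 1) * T - 0.5 * dt:
            cyc_minmax.append((cur_min, cur_max))
            cur_min, cur_max = np.inf, -np.inf
            cycle_idx += 1

        # peak-systole snapshot in the final cycle
        if not steady and t >= last_cycle_start:
            phase = (t - last_cycle_start) % T
            if abs(phase - t_peak) <= 0.5 * dt and peak_field is None:
                peak_field = solver.snapshot()

        if steady:
            speed = solver.max_speed()
            if (prev_speed is not None and speed > 0 and t >= controls.min_time
                    and abs(speed - prev_speed) / speed < controls.steady_tol):
                break
            prev_speed = speed

    periodicity = np.inf
    if len(cyc_minmax) >= 2:
        (lo0, hi0), (lo1, hi1) = cyc_minmax[-2], cyc_minmax[-1]
        rng = max(hi1 - lo1, 1e-12)
        periodicity = max(abs(hi1 - hi0), abs(lo1 - lo0)) / rng
        if periodicity > controls.periodicity_tol:
            warn.append(
                f"solution not periodic after {controls.n_cycles} cycles: "
                f"cycle-to-cycle pressure change {periodicity:.3f} "
                f"> tol {controls.periodicity_tol}")
    if steady:
        periodicity = 0.0

    field = solver.snapshot()
    if peak_field is None:
        peak_field = field
    probes = pd.DataFrame(rec)
    outlet_traces = {l: pd.DataFrame(outlet_rec[l]) for l in labels}
    return SimulationResult(field=field, peak_field=peak_field, probes=probes,
                            outlet_traces=outlet_traces, periodicity=periodicity,
                            warnings=warn, max_divergence=max_div_seen, dt=dt,
                            initial_states=initial_states)
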
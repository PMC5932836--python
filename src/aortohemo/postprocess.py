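"""Hemodynamic quantities extracted from solved flow fields.

Wall shear stress uses the first-order one-sided closure consistent with the
stair-step immersed wall: for a wall face, the tangential velocity magnitude
at the adjacent fluid-cell center divided by the wall-normal distance h/2,
times μ.  Peak-systolic maps are evaluated at the instant of maximum inflow.
Localized normalized helicity (LNH) is the cosine of the angle between
velocity and vorticity, ±1 for purely helical flow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import AortaGeometry, VoxelDomain
from .solver import FlowField, FluidProperties
from .units import M_S_TO_CM_S, MM_TO_M, PA_TO_MMHG

__all__ = [
    "WSSMap",
    "ProbeResult",
    "HelicityMap",
    "wall_shear_stress",
    "pswss_extrema",
    "extract_probes",
    "streamlines_and_lnh",
]

LNH_EPS = 1e-10  # SI; |u| or |ω| below this → LNH defined as 0


@dataclass
class WSSMap:
    """Per-wall-face shear stress with anatomical tags.

    ``cells`` are the adjacent fluid-cell indices, ``axis``/``side`` the wall
    face orientation, ``tau`` the stress magnitude (Pa), ``region`` the
    anatomical tag and ``quadrant`` the O/R/L/I wall partition.
    """

    cells: np.ndarray
    axis: np.ndarray
    side: np.ndarray
    tau: np.ndarray
    region: np.ndarray
    quadrant: np.ndarray
    t: float

    def __len__(self) -> int:
        return len(self.tau)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "i": self.cells[:, 0], "j": self.cells[:, 1], "k": self.cells[:, 2],
            "axis": self.axis, "side": self.side, "tau_Pa": self.tau,
            "region": self.region, "quadrant": self.quadrant,
        })


@dataclass(frozen=True)
class ProbeResult:
    """Peak-systolic probe readings for one case."""

    psv_cm_s: float
    psp_mmHg: float
    psv_time_s: float
    psp_time_s: float
    psv_plane: str = "AscAo"
    psp_plane: str = "AI"


@dataclass
class HelicityMap:
    """Localized normalized helicity per fluid cell + integrated streamlines."""

    lnh: np.ndarray             # full grid, NaN outside fluid
    streamlines: list[np.ndarray]
    domain: VoxelDomain

    def mean_abs_lnh(self, cell_mask: np.ndarray) -> float:
        vals = self.lnh[cell_mask & np.isfinite(self.lnh)]
        return float(np.abs(vals).mean()) if len(vals) else 0.0


def _cell_speed_components(field: FlowField):
    uc = 0.5 * (field.u[:-1] + field.u[1:])
    vc = 0.5 * (field.v[:, :-1] + field.v[:, 1:])
    wc = 0.5 * (field.w[:, :, :-1] + field.w[:, :, 1:])
    return uc, vc, wc


def wall_shear_stress(field: FlowField, domain: VoxelDomain,
                      props: FluidProperties = FluidProperties()) -> WSSMap:
    """First-order wall shear stress on every (non-cap) wall face."""
    if field.domain is not domain and field.u.shape[0] != domain.shape[0] + 1:
        raise ValueError("field and domain are inconsistent")
    uc, vc, wc = _cell_speed_components(field)
    h_m = domain.h * MM_TO_M
    cells_all, axes_all, sides_all, tau_all = [], [], [], []
    for cells, axis, side in domain.wall_faces():
        ii, jj, kk = cells.T
        vel = np.stack([uc[ii, jj, kk], vc[ii, jj, kk], wc[ii, jj, kk]], axis=1)
        vel[:, axis] = 0.0  # tangential part only
        tau = props.mu * np.linalg.norm(vel, axis=1) / (0.5 * h_m)
        cells_all.append(cells)
        axes_all.append(np.full(len(cells), axis))
        sides_all.append(np.full(len(cells), side))
        tau_all.append(tau)
    if not cells_all:
        raise ValueError("domain has no wall faces")
    cells = np.vstack(cells_all)
    # tag faces by the position of the wall face center
    centers = domain.cell_centers(cells)
    axes = np.concatenate(axes_all)
    sides = np.concatenate(sides_all)
    offs = np.zeros_like(centers)
    offs[np.arange(len(cells)), axes] = sides * 0.5 * domain.h
    region, quadrant = domain.geom.classify_wall_points(centers + offs)
    return WSSMap(cells=cells, axis=axes, side=sides,
                  tau=np.concatenate(tau_all), region=region, quadrant=quadrant,
                  t=field.t)


def pswss_extrema(wss: WSSMap, domain: VoxelDomain,
                  cap_exclusion_diameters: float = 1.0) -> dict:
    """Global min/max peak-systolic WSS with their anatomical tags.

    Faces within ``cap_exclusion_diameters`` local cap diameters of any
    inlet/outlet cap are excluded: the plug inlet and the outlet pressure
    conditions produce boundary-layer artifacts there that a body-fitted
    simulation would place outside the analyzed lumen.
    """
    if len(wss) == 0:
        raise ValueError("empty WSS map")
    centers = domain.cell_centers(wss.cells)
    keep = np.ones(len(wss), dtype=bool)
    for cap in domain.geom.caps:
        d = np.linalg.norm(centers - cap.center, axis=1)
        keep &= d > cap_exclusion_diameters * 2.0 * cap.radius
    if not keep.any():
        raise ValueError("cap exclusion removed all wall faces")
    tau = wss.tau[keep]
    region = wss.region[keep]
    quad = wss.quadrant[keep]
    i_min, i_max = int(np.argmin(tau)), int(np.argmax(tau))
    return {
        "min_tau_Pa": float(tau[i_min]),
        "min_region": str(region[i_min]),
        "min_quadrant": str(quad[i_min]),
        "max_tau_Pa": float(tau[i_max]),
        "max_region": str(region[i_max]),
        "max_quadrant": str(quad[i_max]),
        "n_faces": int(keep.sum()),
    }


def extract_probes(fields: list[FlowField], geom: AortaGeometry,
                   domain: VoxelDomain | None = None) -> ProbeResult:
    """Peak systolic velocity and pressure from a series of field snapshots.

    PSV is the cycle maximum of the fastest velocity on the ascending-aorta
    plane (what a TTE Doppler gate reads); PSP the cycle maximum of the
    area-averaged pressure on the isthmus plane (a catheter-like lumped
    reading).
    """
    if not fields:
        raise ValueError("no fields supplied")
    dom = domain or fields[0].domain
    asc = dom.plane_cells("AscAo")
    ai = dom.plane_cells("AI")
    if len(asc) == 0 or len(ai) == 0:
        raise ValueError("probe plane lies outside the domain")
    best_v, tv = -np.inf, 0.0
    best_p, tp = -np.inf, 0.0
    for f in fields:
        uc, vc, wc = _cell_speed_components(f)
        ii, jj, kk = asc.T
        speed = np.sqrt(uc[ii, jj, kk] ** 2 + vc[ii, jj, kk] ** 2 + wc[ii, jj, kk] ** 2)
        vmax = float(speed.max())
        if vmax > best_v:
            best_v, tv = vmax, f.t
        pm = float(f.p[tuple(ai.T)].mean())
        if pm > best_p:
            best_p, tp = pm, f.t
    return ProbeResult(psv_cm_s=best_v * M_S_TO_CM_S, psp_mmHg=best_p * PA_TO_MMHG,
                       psv_time_s=tv, psp_time_s=tp)


def _vorticity(field: FlowField, h_m: float):
    """Central-difference vorticity at cell centers (edge cells one-sided 0)."""
    uc, vc, wc = _cell_speed_components(field)

    def d(q, axis):
        out = np.zeros_like(q)
        sl_hi = [slice(None)] * 3
        sl_lo = [slice(None)] * 3
        mid = [slice(None)] * 3
        sl_hi[axis] = slice(2, None)
        sl_lo[axis] = slice(0, -2)
        mid[axis] = slice(1, -1)
        out[tuple(mid)] = (q[tuple(sl_hi)] - q[tuple(sl_lo)]) / (2 * h_m)
        return out

    wx = d(wc, 1) - d(vc, 2)
    wy = d(uc, 2) - d(wc, 0)
    wz = d(vc, 0) - d(uc, 1)
    return (uc, vc, wc), (wx, wy, wz)


def streamlines_and_lnh(field: FlowField, seeds: np.ndarray,
                        step_mm: float | None = None, max_steps: int = 4000) -> HelicityMap:
    """Integrate streamlines (fixed-step RK4) and compute per-cell LNH.

    ``seeds`` are physical points in mm; seeds outside the fluid are skipped
    with a warning.  Streamlines stop on leaving the fluid or at the step cap.
    """
    import warnings as _warnings

    dom = field.domain
    h_m = dom.h * MM_TO_M
    (uc, vc, wc), (wx, wy, wz) = _vorticity(field, h_m)
    speed = np.sqrt(uc ** 2 + vc ** 2 + wc ** 2)
    wmag = np.sqrt(wx ** 2 + wy ** 2 + wz ** 2)
    hel = uc * wx + vc * wy + wc * wz
    with np.errstate(invalid="ignore", divide="ignore"):
        lnh = np.where((speed > LNH_EPS) & (wmag > LNH_EPS), hel / (speed * wmag), 0.0)
    lnh = np.clip(lnh, -1.0, 1.0)
    lnh[~dom.fluid] = np.nan

    # trilinear interpolation on cell-centered velocity
    from scipy.interpolate import RegularGridInterpolator

    axes = [dom.origin[d] + (np.arange(dom.shape[d]) + 0.5) * dom.h for d in range(3)]
    vel_grid = np.stack([uc, vc, wc], axis=-1)
    interp = RegularGridInterpolator(axes, vel_grid, bounds_error=False,
                                     fill_value=0.0)

    def inside(p):
        idx = np.floor((p - dom.origin) / dom.h).astype(int)
        if np.any(idx < 0) or np.any(idx >= dom.shape):
            return False
        return bool(dom.fluid[tuple(idx)])

    ds = step_mm if step_mm is not None else 0.5 * dom.h
    lines = []
    for seed in np.atleast_2d(np.asarray(seeds, dtype=float)):
        if not inside(seed):
            _warnings.warn(f"streamline seed {seed} lies outside the fluid; skipped",
                           stacklevel=2)
            continue
        pts = [seed.copy()]
        p = seed.copy()
        for _ in range(max_steps):
            def v_dir(x):
                v = interp(x[None])[0]
                n = np.linalg.norm(v)
                return v / n if n > LNH_EPS else np.zeros(3)

            k1 = v_dir(p)
            if not k1.any():
                break
            k2 = v_dir(p + 0.5 * ds * k1)
            k3 = v_dir(p + 0.5 * ds * k2)
            k4 = v_dir(p + ds * k3)
            p = p + (ds / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            if not inside(p):
                break
            pts.append(p.copy())
        lines.append(np.asarray(pts))
    return HelicityMap(lnh=lnh, streamlines=lines, domain=dom)
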
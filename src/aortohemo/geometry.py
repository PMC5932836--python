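"""Parametric synthetic aortas and their voxelized flow domains.

The geometry is an analytic stand-in for an image-derived aortic
reconstruction: a circular-arc arch in the x–z plane joining a vertical
ascending limb (inlet at the origin, axis +z) to a vertical descending limb,
with the three arch branches (BA, LCCA, LSA) emerging vertically from the top
of the arch, and an aortic-isthmus (AI) region on the proximal descending
limb that can be narrowed by a stenosis factor.  The lumen is the union of
flat-capped tapered tubes around a polyline centerline; everything downstream
(measurement planes, wall quadrants O/R/L/I, anatomical region tags,
voxelization, surface export) is derived from that implicit solid.

Conventions fixed here for reproducibility:

* right-handed coordinates in mm, inlet plane normal −z at the origin;
* voxel cells are cell-centered: index (i,j,k) maps to
  ``origin + (i+0.5)·h`` per axis, 0-based;
* the reported diameter is the equivalent-circle diameter ``2·sqrt(A/π)`` of
  the cross-section area;
* wall quadrants: I(nner) faces the arch center, O(uter) faces away, L/R are
  the ±y lateral walls (R = −y).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "AortaSpec",
    "AortaGeometry",
    "VoxelDomain",
    "Branch",
    "Cap",
    "build_aorta",
    "measure_diameter",
    "voxelize",
    "export_surface",
    "import_surface",
    "mesh_plane_diameter",
]

BRANCH_NAMES = ("BA", "LCCA", "LSA")
#: Arch angles (fraction of the half-circle) where the branches attach.
BRANCH_ANGLES = {"BA": 0.25 * np.pi, "LCCA": 0.50 * np.pi, "LSA": 0.75 * np.pi}
PROBE_PLANES = ("AscAo", "AI", "DAo")


@dataclass(frozen=True)
class AortaSpec:
    """Parametric description of a synthetic aorta (all lengths in mm)."""

    inlet_diameter: float
    dao_diameter: float
    ai_diameter: float
    branch_diameters: dict[str, float] = field(default_factory=dict)
    arch_radius: float = 0.0
    ascending_length: float = 25.0
    descending_length: float = 45.0
    branch_length: float = 16.0
    ai_stenosis_factor: float = 1.0
    ai_offset: float | None = None  # distance below the arch end to the AI plane

    def __post_init__(self) -> None:
        for name in ("inlet_diameter", "dao_diameter", "ai_diameter",
                     "ascending_length", "descending_length"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be > 0, got {v!r}")
        if not (0.0 < self.ai_stenosis_factor <= 1.0):
            raise ValueError(
                f"ai_stenosis_factor must be in (0, 1], got {self.ai_stenosis_factor!r}")
        if self.branch_diameters:
            if set(self.branch_diameters) != set(BRANCH_NAMES):
                raise ValueError(f"branch_diameters keys must be {set(BRANCH_NAMES)}")
            if self.arch_radius <= 0:
                raise ValueError("arch_radius must be > 0 when branches are present")
            if self.branch_length <= 0:
                raise ValueError("branch_length must be > 0")
            for k, d in self.branch_diameters.items():
                if not np.isfinite(d) or d <= 0:
                    raise ValueError(f"branch diameter {k} must be > 0, got {d!r}")
                if d >= self.inlet_diameter:
                    raise ValueError(
                        f"branch {k} diameter {d} must be smaller than the inlet "
                        f"diameter {self.inlet_diameter}")
            # neighbouring branches must not overlap along the arch
            arc_gap = 0.25 * np.pi * self.arch_radius
            for a, b in (("BA", "LCCA"), ("LCCA", "LSA")):
                need = 0.5 * (self.branch_diameters[a] + self.branch_diameters[b])
                if arc_gap < need:
                    raise ValueError(
                        f"branches {a} and {b} overlap: arch arc spacing {arc_gap:.2f} mm "
                        f"< required {need:.2f} mm (increase arch_radius)")
        elif self.arch_radius > 0:
            raise ValueError("an arch without branches is not supported; "
                             "set arch_radius=0 for a straight tube")

    @classmethod
    def straight_tube(cls, diameter: float, length: float,
                      outlet_diameter: float | None = None) -> "AortaSpec":
        """Degenerate spec: a straight (possibly conical) tube along +z."""
        d_out = diameter if outlet_diameter is None else outlet_diameter
        half = 0.5 * length
        return cls(inlet_diameter=diameter, dao_diameter=d_out,
                   ai_diameter=0.5 * (diameter + d_out),
                   ascending_length=half, descending_length=half)

    @classmethod
    def cohort_mean(cls) -> "AortaSpec":
        """The cohort-mean aorta (AscAo 19.2 mm, AI 12.1 mm, DAo 10.9 mm)."""
        d = 19.2
        return cls(
            inlet_diameter=d,
            dao_diameter=10.9,
            ai_diameter=12.1,
            branch_diameters={"BA": 0.50 * d, "LCCA": 0.40 * d, "LSA": 0.42 * d},
            arch_radius=0.75 * d,
            ascending_length=1.3 * d,
            descending_length=2.3 * d,
            branch_length=1.8 * 0.5 * d,
        )


@dataclass(frozen=True)
class Branch:
    label: str
    attach_point: np.ndarray  # on the main centerline, mm
    attach_s: float           # main-centerline arclength of the attachment
    direction: np.ndarray     # unit vector (always +z here)
    radius: float
    length: float

    @property
    def end_point(self) -> np.ndarray:
        return self.attach_point + self.length * self.direction


@dataclass(frozen=True)
class Cap:
    """Planar inlet/outlet cap; normal points out of the fluid."""

    label: str
    center: np.ndarray
    normal: np.ndarray
    radius: float

    @property
    def axis(self) -> int:
        return int(np.argmax(np.abs(self.normal)))

    @property
    def side(self) -> int:
        return int(np.sign(self.normal[self.axis]))


class AortaGeometry:
    """Analytic aorta: centerline + radius profile + branches + caps."""

    def __init__(self, spec: AortaSpec):
        self.spec = spec
        self._build_centerline()
        self._build_branches_and_caps()
        self._build_probes()

    # -- construction -----------------------------------------------------

    def _build_centerline(self) -> None:
        sp = self.spec
        r_in = 0.5 * sp.inlet_diameter
        r_ai = 0.5 * sp.ai_diameter
        r_dao = 0.5 * sp.dao_diameter
        pts = [np.array([0.0, 0.0, 0.0]), np.array([0.0, 0.0, sp.ascending_length])]
        if sp.arch_radius > 0:
            Ra, La = sp.arch_radius, sp.ascending_length
            phi = np.linspace(0.0, np.pi, 65)[1:]
            arch = np.stack([Ra * (1 - np.cos(phi)), np.zeros_like(phi),
                             La + Ra * np.sin(phi)], axis=1)
            pts.extend(arch)
            end = np.array([2 * Ra, 0.0, La - sp.descending_length])
        else:
            end = np.array([0.0, 0.0, sp.ascending_length + sp.descending_length])
        pts.append(end)
        self.centerline = np.asarray(pts)
        seg = np.diff(self.centerline, axis=0)
        seg_len = np.linalg.norm(seg, axis=1)
        self.arclength = np.concatenate([[0.0], np.cumsum(seg_len)])
        self.total_length = float(self.arclength[-1])
        self.s_arch_start = sp.ascending_length
        self.s_arch_end = (sp.ascending_length + np.pi * sp.arch_radius
                           if sp.arch_radius > 0 else sp.ascending_length)
        self.arch_center = np.array([sp.arch_radius, 0.0, sp.ascending_length])

        if sp.arch_radius > 0:
            ai_off = sp.ai_offset if sp.ai_offset is not None else 0.6 * sp.inlet_diameter
            ai_off = min(ai_off, 0.8 * sp.descending_length)
            self.s_ai = self.s_arch_end + ai_off
            s_lsa = sp.ascending_length + BRANCH_ANGLES["LSA"] * sp.arch_radius
            ctrl_s = [0.0, s_lsa, self.s_ai, self.total_length]
            ctrl_r = [r_in, r_in, r_ai, r_dao]
        else:
            self.s_ai = 0.5 * self.total_length
            ctrl_s = [0.0, self.total_length]
            ctrl_r = [r_in, r_dao]
        self._ctrl_s = np.asarray(ctrl_s)
        self._ctrl_r = np.asarray(ctrl_r)

    def radius_at(self, s) -> np.ndarray:
        """Lumen radius (mm) of the main tube at centerline arclength s."""
        s = np.asarray(s, dtype=float)
        r = np.interp(s, self._ctrl_s, self._ctrl_r)
        f = self.spec.ai_stenosis_factor
        if f < 1.0:
            r_ai = 0.5 * self.spec.ai_diameter
            w = 2.0 * r_ai  # stenosis half-length
            dip = r_ai * (f + (1.0 - f) * np.minimum(np.abs(s - self.s_ai) / w, 1.0))
            near = np.abs(s - self.s_ai) < w
            r = np.where(near, np.minimum(r, dip), r)
        return r

    def _build_branches_and_caps(self) -> None:
        sp = self.spec
        self.branches: list[Branch] = []
        caps = [Cap("inlet", np.zeros(3), np.array([0.0, 0.0, -1.0]),
                    0.5 * sp.inlet_diameter)]
        if sp.branch_diameters:
            Ra, La = sp.arch_radius, sp.ascending_length
            for name in BRANCH_NAMES:
                ang = BRANCH_ANGLES[name]
                attach = np.array([Ra * (1 - np.cos(ang)), 0.0, La + Ra * np.sin(ang)])
                br = Branch(name, attach, La + ang * Ra, np.array([0.0, 0.0, 1.0]),
                            0.5 * sp.branch_diameters[name], sp.branch_length)
                self.branches.append(br)
                caps.append(Cap(name, br.end_point, np.array([0.0, 0.0, 1.0]), br.radius))
            dao_normal = np.array([0.0, 0.0, -1.0])
        else:
            dao_normal = np.array([0.0, 0.0, 1.0])
        caps.append(Cap("DAo", self.centerline[-1].copy(), dao_normal,
                        float(self.radius_at(self.total_length))))
        self.caps = caps
        self.outlet_labels = [c.label for c in caps if c.label != "inlet"]
        # clinical segment boundaries: the ascending aorta ends at the BA
        # origin and the arch at the LSA origin (the geometric arc start/end
        # are not the anatomical landmarks)
        if self.branches:
            self.s_ascao_end = self.branches[0].attach_s   # BA
            self.s_arch_end_clinical = self.branches[-1].attach_s  # LSA
        else:
            self.s_ascao_end = self.s_arch_start
            self.s_arch_end_clinical = self.s_arch_end

    def _build_probes(self) -> None:
        eps = 1e-9
        self.probe_s = {
            "AscAo": 0.5 * self.spec.ascending_length,
            "AI": self.s_ai,
            "DAo": self.total_length - eps,
        }

    # -- queries ----------------------------------------------------------

    def point_at(self, s: float) -> np.ndarray:
        """Centerline point at arclength s."""
        s = np.clip(s, 0.0, self.total_length)
        i = int(np.searchsorted(self.arclength, s, side="right") - 1)
        i = min(i, len(self.centerline) - 2)
        ds = self.arclength[i + 1] - self.arclength[i]
        t = 0.0 if ds == 0 else (s - self.arclength[i]) / ds
        return (1 - t) * self.centerline[i] + t * self.centerline[i + 1]

    def min_lumen_diameter(self) -> float:
        s = np.linspace(0, self.total_length, 512)
        d_main = 2.0 * float(self.radius_at(s).min())
        d_br = min((2 * b.radius for b in self.branches), default=np.inf)
        return min(d_main, d_br)

    def _project_main(self, pts: np.ndarray):
        """Per point: (signed surface distance, nearest arclength, radial vec).

        The surface distance of a flat-capped tapered tube segment is
        ``max(radial − r(s), axial overshoot)``; the union over segments is a
        min.  Points project segment-by-segment (vectorized per segment).
        """
        n = len(pts)
        best = np.full(n, np.inf)
        s_near = np.zeros(n)
        rad_vec = np.zeros((n, 3))
        P0, P1 = self.centerline[:-1], self.centerline[1:]
        for i in range(len(P0)):
            a, b = P0[i], P1[i]
            d = b - a
            L = np.linalg.norm(d)
            if L == 0:
                continue
            dn = d / L
            w = pts - a
            t_raw = w @ dn
            t = np.clip(t_raw, 0.0, L)
            s_here = self.arclength[i] + t
            radial = w - np.outer(t, dn)
            rd = np.linalg.norm(radial, axis=1)
            d_surf = rd - self.radius_at(s_here)
            axial_out = np.maximum(-t_raw, t_raw - L)
            d_seg = np.maximum(d_surf, axial_out)
            upd = d_seg < best
            best[upd] = d_seg[upd]
            s_near[upd] = s_here[upd]
            rad_vec[upd] = radial[upd]
        return best, s_near, rad_vec

    def _project_branches(self, pts: np.ndarray):
        n = len(pts)
        best = np.full(n, np.inf)
        which = np.full(n, -1)
        axial = np.zeros(n)
        for bi, br in enumerate(self.branches):
            w = pts - br.attach_point
            t_raw = w @ br.direction
            radial = w - np.outer(t_raw, br.direction)
            rd = np.linalg.norm(radial, axis=1)
            d_seg = np.maximum(rd - br.radius, np.maximum(-t_raw, t_raw - br.length))
            upd = d_seg < best
            best[upd] = d_seg[upd]
            which[upd] = bi
            axial[upd] = t_raw[upd]
        return best, which, axial

    def sdf(self, pts: np.ndarray) -> np.ndarray:
        """Approximate signed distance to the lumen surface (negative inside)."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        d_main, _, _ = self._project_main(pts)
        if self.branches:
            d_br, _, _ = self._project_branches(pts)
            return np.minimum(d_main, d_br)
        return d_main

    def contains(self, pts: np.ndarray) -> np.ndarray:
        return self.sdf(pts) <= 0.0

    def classify_wall_points(self, pts: np.ndarray):
        """Anatomical (region, quadrant) tags for points on/near the wall.

        Regions: ``ascao``, ``arch``, ``isthmus``, ``dao``, ``branch-XX``,
        ``ostium-XX``.  Quadrants O/R/L/I follow the arch-plane convention
        (I toward the arch center, R = −y); branch points carry quadrant "".
        """
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        d_main, s_near, rad_vec = self._project_main(pts)
        n = len(pts)
        region = np.empty(n, dtype=object)
        quad = np.empty(n, dtype=object)

        on_branch = np.zeros(n, dtype=bool)
        if self.branches:
            d_br, which, axial = self._project_branches(pts)
            on_branch = d_br < d_main
        # main-tube tags
        m = ~on_branch
        s = s_near[m]
        reg = np.where(
            s < self.s_ascao_end, "ascao",
            np.where(s < self.s_arch_end_clinical, "arch",
                     np.where(s <= self.s_ai + self.spec.ai_diameter, "isthmus", "dao")))
        region[m] = reg
        v = rad_vec[m]
        # inner direction: within the arch (x–z) plane, toward the arch center
        to_center = self.arch_center - pts[m]
        to_center[:, 1] = 0.0
        nrm = np.linalg.norm(v, axis=1, keepdims=True)
        nrm[nrm == 0] = 1.0
        vn = v / nrm
        innorm = np.linalg.norm(to_center, axis=1, keepdims=True)
        innorm[innorm == 0] = 1.0
        inner = to_center / innorm
        dot_io = np.sum(vn * inner, axis=1)
        dot_y = vn[:, 1]
        labels = np.array(["I", "O", "L", "R"], dtype=object)
        scores = np.stack([dot_io, -dot_io, dot_y, -dot_y], axis=1)
        quad[m] = labels[np.argmax(scores, axis=1)]
        # ostium override for main-tube points adjacent to a branch root
        for br in self.branches:
            near = m & (np.linalg.norm(pts - br.attach_point, axis=1)
                        < br.radius + 0.5 * self.radius_at(br.attach_s))
            region[near] = f"ostium-{br.label}"
        # branch tags
        if self.branches and on_branch.any():
            for bi, br in enumerate(self.branches):
                sel = on_branch & (which == bi)
                root = sel & (axial < 2.0 * br.radius)
                region[sel] = f"branch-{br.label}"
                region[root] = f"ostium-{br.label}"
                quad[sel] = ""
        return region, quad


def build_aorta(spec: AortaSpec) -> AortaGeometry:
    """Construct the analytic geometry for a spec (validates invariants)."""
    return AortaGeometry(spec)


def measure_diameter(geom: AortaGeometry, location: str) -> float:
    """Analytic lumen diameter (mm) at a named probe plane.

    Probe planes: ``AscAo`` (mid-ascending), ``AI`` (aortic isthmus, includes
    the stenosis factor), ``DAo`` (descending outlet).
    """
    if location not in geom.probe_s:
        raise KeyError(f"unknown probe plane {location!r}; valid: {PROBE_PLANES}")
    return 2.0 * float(geom.radius_at(geom.probe_s[location]))


# ---------------------------------------------------------------------------
# voxelization


@dataclass
class VoxelCap:
    """Cap faces on the voxel grid: fluid-cell indices + face axis/side."""

    label: str
    axis: int
    side: int            # +1: face on the + side of the cell
    cells: np.ndarray    # (M, 3) int indices of the adjacent fluid cells


class VoxelDomain:
    """Cell-centered voxelization of an aorta with labeled boundary faces."""

    def __init__(self, geom: AortaGeometry, h: float, origin: np.ndarray,
                 fluid: np.ndarray, caps: list[VoxelCap]):
        self.geom = geom
        self.h = float(h)
        self.origin = np.asarray(origin, dtype=float)
        self.fluid = fluid
        self.caps = caps
        self.shape = fluid.shape

    def cell_centers(self, idx: np.ndarray) -> np.ndarray:
        """Physical centers (mm) of cells given (M,3) integer indices."""
        return self.origin + (np.asarray(idx) + 0.5) * self.h

    @property
    def n_fluid(self) -> int:
        return int(self.fluid.sum())

    def fluid_volume(self) -> float:
        """Fluid volume in mm³."""
        return self.n_fluid * self.h ** 3

    def cap_area(self, label: str) -> float:
        """Discrete area (mm²) of a labeled cap."""
        return sum(len(c.cells) for c in self.caps if c.label == label) * self.h ** 2

    def plane_cells(self, location: str) -> np.ndarray:
        """Indices of fluid cells in the one-cell slab of a probe plane,
        restricted to the local tube limb."""
        geom = self.geom
        if location not in geom.probe_s:
            raise KeyError(f"unknown probe plane {location!r}; valid: {PROBE_PLANES}")
        s = geom.probe_s[location]
        center = geom.point_at(s)
        r_loc = float(geom.radius_at(s))
        k = int(np.floor((center[2] - self.origin[2]) / self.h))
        k = np.clip(k, 0, self.shape[2] - 1)
        ii, jj = np.nonzero(self.fluid[:, :, k])
        idx = np.stack([ii, jj, np.full_like(ii, k)], axis=1)
        pts = self.cell_centers(idx)
        keep = np.linalg.norm(pts[:, :2] - center[:2], axis=1) <= 1.4 * r_loc + self.h
        return idx[keep]

    def plane_diameter(self, location: str) -> float:
        """Equivalent-circle diameter (mm) of the voxelized probe section."""
        n = len(self.plane_cells(location))
        if n == 0:
            raise ValueError(f"probe plane {location!r} lies outside the fluid domain")
        return 2.0 * np.sqrt(n * self.h ** 2 / np.pi)

    def wall_faces(self):
        """Enumerate wall faces as (cells, axis, side) triples.

        A wall face separates a fluid cell from a non-fluid cell and is not
        part of any labeled cap.
        """
        cap_keys = set()
        for c in self.caps:
            for cell in c.cells:
                cap_keys.add((int(cell[0]), int(cell[1]), int(cell[2]), c.axis, c.side))
        F = self.fluid
        out = []
        pad = np.pad(F, 1, constant_values=False)
        for axis in range(3):
            for side in (-1, 1):
                sl = [slice(1, -1)] * 3
                sl[axis] = slice(2, None) if side > 0 else slice(0, -2)
                nb = pad[tuple(sl)]
                wall = F & ~nb
                cells = np.argwhere(wall)
                if len(cells) == 0:
                    continue
                keep = np.array([
                    (int(c[0]), int(c[1]), int(c[2]), axis, side) not in cap_keys
                    for c in cells])
                cells = cells[keep]
                if len(cells):
                    out.append((cells, axis, side))
        return out


def voxelize(geom: AortaGeometry, h: float) -> VoxelDomain:
    """Voxelize an aorta on a uniform cell-centered grid of spacing h (mm).

    Requires at least 8 cells across the smallest lumen diameter (warns below
    10).  The fluid mask is pruned to the component connected to the inlet;
    a labeled cap that becomes unreachable raises (disconnected domain).
    """
    d_min = geom.min_lumen_diameter()
    cells_across = d_min / h
    if cells_across < 8.0:
        raise ValueError(
            f"grid too coarse: {cells_across:.1f} cells across the minimum lumen "
            f"diameter {d_min:.2f} mm (need >= 8, i.e. h <= {d_min / 8:.3f} mm)")
    if cells_across < 10.0:
        warnings.warn(f"only {cells_across:.1f} cells across the minimum lumen; "
                      "results will be first-order accurate at best", stacklevel=2)

    all_pts = np.vstack([geom.centerline] + [np.vstack([b.attach_point, b.end_point])
                                             for b in geom.branches])
    r_max = float(geom.radius_at(np.linspace(0, geom.total_length, 256)).max())
    lo = all_pts.min(axis=0) - r_max - 2 * h
    hi = all_pts.max(axis=0) + r_max + 2 * h
    origin = np.floor(lo / h) * h  # face planes land on multiples of h
    shape = tuple(np.ceil((hi - origin) / h).astype(int))

    i, j, k = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    centers = origin + (np.stack([i, j, k], axis=-1) + 0.5) * h
    fluid = geom.contains(centers.reshape(-1, 3)).reshape(shape)

    # connectivity: keep the inlet component, prune stray voxels
    lab, n_comp = ndimage.label(fluid)
    if n_comp == 0:
        raise ValueError("voxelization produced an empty fluid domain")
    caps: list[VoxelCap] = []
    if n_comp > 1:
        inlet_cap = next(c for c in geom.caps if c.label == "inlet")
        seed = inlet_cap.center + np.array([0.0, 0.0, 1.0]) * 2 * h
        sidx = tuple(np.clip(((seed - origin) / h - 0.5).round().astype(int),
                             0, np.array(shape) - 1))
        main = lab[sidx]
        if main == 0:
            counts = np.bincount(lab.ravel())[1:]
            main = int(np.argmax(counts)) + 1
        fluid = lab == main

    for cap in geom.caps:
        axis, side = cap.axis, cap.side
        plane = cap.center[axis]
        # fluid cells whose outward face in this direction leaves the fluid
        pad = np.pad(fluid, 1, constant_values=False)
        sl = [slice(1, -1)] * 3
        sl[axis] = slice(2, None) if side > 0 else slice(0, -2)
        boundary = fluid & ~pad[tuple(sl)]
        cells = np.argwhere(boundary)
        if len(cells) == 0:
            raise ValueError(f"cap {cap.label!r} has no boundary faces: "
                             "fluid domain disconnected or spec degenerate")
        face_pos = origin[axis] + (cells[:, axis] + (1 if side > 0 else 0)) * h
        close = np.abs(face_pos - plane) <= 1.01 * h
        pts = origin + (cells + 0.5) * h
        rad = np.linalg.norm(np.delete(pts - cap.center, axis, axis=1), axis=1)
        sel = close & (rad <= cap.radius + 1.5 * h)
        if not sel.any():
            raise ValueError(f"cap {cap.label!r} unreachable on the voxel grid: "
                             "fluid domain disconnected")
        caps.append(VoxelCap(cap.label, axis, side, cells[sel]))

    return VoxelDomain(geom, h, origin, fluid, caps)


# ---------------------------------------------------------------------------
# surface export / import (STL via trimesh, marching cubes on the SDF)


def _surface_mesh(geom: AortaGeometry, resolution: float | None = None):
    import trimesh
    from skimage import measure

    if resolution is None:
        resolution = geom.min_lumen_diameter() / 14.0
    all_pts = np.vstack([geom.centerline] + [np.vstack([b.attach_point, b.end_point])
                                             for b in geom.branches])
    r_max = float(geom.radius_at(np.linspace(0, geom.total_length, 256)).max())
    lo = all_pts.min(axis=0) - r_max - 3 * resolution
    hi = all_pts.max(axis=0) + r_max + 3 * resolution
    shape = np.ceil((hi - lo) / resolution).astype(int) + 1
    ax = [lo[d] + np.arange(shape[d]) * resolution for d in range(3)]
    grid = np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1)
    sdf = geom.sdf(grid.reshape(-1, 3)).reshape(grid.shape[:3])
    # push node values off the level set: marching cubes would otherwise emit
    # near-coincident vertices that collapse to degenerate faces (and open
    # edges) after the float32 STL round trip
    eps = 1e-4 * resolution
    sdf = np.where(np.abs(sdf) < eps, eps, sdf)
    verts, faces, _, _ = measure.marching_cubes(sdf, level=0.0, spacing=(resolution,) * 3)
    verts = verts + lo
    return trimesh.Trimesh(vertices=verts, faces=faces, process=False)


def export_surface(geom: AortaGeometry, path, resolution: float | None = None):
    """Write a watertight triangulated lumen surface (binary STL), mm units."""
    mesh = _surface_mesh(geom, resolution)
    try:
        mesh.export(str(path))
    except OSError as e:
        raise OSError(f"cannot write surface to {path!r}: {e}") from e
    return mesh


def import_surface(path):
    """Load a triangulated surface written by :func:`export_surface`."""
    import trimesh

    try:
        mesh = trimesh.load(str(path), force="mesh")
    except OSError as e:
        raise OSError(f"cannot read surface from {path!r}: {e}") from e
    return mesh


def mesh_plane_diameter(mesh, origin, normal) -> float:
    """Equivalent-circle diameter (mm) of a mesh cross-section."""
    origin = np.asarray(origin, dtype=float)
    normal = np.asarray(normal, dtype=float)
    section = None
    # a plane passing exactly through mesh vertices can defeat the slicer;
    # nudge along the normal until a contour appears
    for off in (0.0, 1e-6, -1e-6, 1e-3, -1e-3):
        section = mesh.section(plane_origin=origin + off * normal,
                               plane_normal=normal)
        if section is not None:
            break
    if section is None:
        raise ValueError("plane does not intersect the surface")
    planar, _ = section.to_2D()
    area = float(planar.area)
    return 2.0 * np.sqrt(area / np.pi)
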
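"""Observable extraction from solved flow fields.

The observables mirror what a clinician-facing study of post-surgical
voiding reads off a CFD solution:

* MV-EUO — velocity magnitude at the midpoint of the external urethral
  orifice (the outlet segment);
* vortex presence and size — the paired recirculation zones that form on
  the flanks of the hollowed prostatic urethra, segmented as closed regions
  bounded by the separatrix streamline (the streamline carrying the wall
  value of psi); their transverse (TD-V) and longitudinal (LD-V) diameters
  are the axis-aligned extents of each region, reported as the mean of the
  two sides;
* transverse velocity profiles at fixed heights, which show the axial-flow
  sign reversal across a recirculation zone.

Lengths of vortex diameters are reported in centimetres; velocities in m/s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .flow_solver import FlowSolution, SolverError, compute_streamfunction
from .geometry import GeometrySpec, PlanarDomain, rpu_ratios
from .meshing import Mesh

__all__ = [
    "VortexMetrics",
    "CaseResult",
    "mv_euo",
    "detect_vortices",
    "velocity_profile",
    "summarize_case",
]

M_TO_CM = 100.0

#: recirculation segmentation: |psi - psi_wall| must exceed this fraction of
#: the total inlet-outlet psi jump to count as inside the separatrix
PSI_REL_TOL = 1e-5

#: minimum transverse extent of a region, in local cell diameters, below
#: which it is discarded as numerical noise
MIN_CELL_DIAMS = 2.0


@dataclass(frozen=True)
class VortexMetrics:
    """Per-side recirculation-zone metrics (diameters in cm)."""

    left: bool
    right: bool
    td_left: float | None = None
    td_right: float | None = None
    ld_left: float | None = None
    ld_right: float | None = None

    @property
    def present(self) -> bool:
        return self.left or self.right

    @property
    def td_v(self) -> float | None:
        """Transverse diameter, mean of the sides where a vortex exists."""
        vals = [d for d in (self.td_left, self.td_right) if d is not None]
        return float(np.mean(vals)) if vals else None

    @property
    def ld_v(self) -> float | None:
        vals = [d for d in (self.ld_left, self.ld_right) if d is not None]
        return float(np.mean(vals)) if vals else None


@dataclass(frozen=True)
class CaseResult:
    """One row of the cohort table: ratios plus solved observables."""

    case_id: str
    ld_pu: float
    td_bn: float
    td_pu: float
    rpu1: float
    rpu2: float
    converged: bool
    n_elements: int
    n_iter: int
    mv_euo: float | None = None
    vortex: bool | None = None
    td_v: float | None = None
    ld_v: float | None = None
    mass_imbalance: float | None = None

    def as_dict(self) -> dict:
        return {
            "case_id": self.case_id, "ld_pu_cm": self.ld_pu,
            "td_bn_cm": self.td_bn, "td_pu_cm": self.td_pu,
            "rpu1": self.rpu1, "rpu2": self.rpu2,
            "converged": self.converged, "elements": self.n_elements,
            "iterations": self.n_iter, "mv_euo_m_s": self.mv_euo,
            "vortex": self.vortex, "td_v_cm": self.td_v,
            "ld_v_cm": self.ld_v, "mass_imbalance": self.mass_imbalance,
        }


def _interpolator(solution: FlowSolution, mesh: Mesh):
    from matplotlib.tri import LinearTriInterpolator, Triangulation

    tri = Triangulation(mesh.nodes[:, 0], mesh.nodes[:, 1], mesh.triangles)
    vel = solution.node_velocity()
    return (LinearTriInterpolator(tri, vel[:, 0]),
            LinearTriInterpolator(tri, vel[:, 1]))


def mv_euo(solution: FlowSolution, mesh: Mesh) -> float:
    """Velocity magnitude (m/s) at the midpoint of the outlet segment."""
    if not solution.converged:
        raise SolverError("MV-EUO requires a converged solution")
    g = solution.geom
    sel = g.b_outlet
    if len(sel) == 0:
        raise SolverError("mesh has no outlet faces")
    nodes = np.unique(g.f_nodes[g.boundary[sel]])
    pts = mesh.nodes[nodes]
    half = mesh.domain is not None and mesh.domain.half
    # on a half mesh the outlet spans axis..wall and the full-orifice
    # midpoint is the axis end
    mid_x = pts[:, 0].min() if half else 0.5 * (pts[:, 0].min()
                                                + pts[:, 0].max())
    mid = np.array([mid_x, pts[:, 1].mean()])
    fu, fv = _interpolator(solution, mesh)
    uu, vv = float(fu(*mid)), float(fv(*mid))
    if np.isnan(uu) or np.isnan(vv):
        # the exact midpoint sits on the boundary edge; nudge a fraction of
        # a face length inward to land robustly inside an element
        h = float(g.b_area[sel].mean())
        for dx, dy in ((0.0, 0.25 * h), (0.25 * h, 0.25 * h),
                       (0.25 * h, 0.0)):
            uu = float(fu(mid[0] + dx, mid[1] + dy))
            vv = float(fv(mid[0] + dx, mid[1] + dy))
            if not (np.isnan(uu) or np.isnan(vv)):
                break
    if np.isnan(uu) or np.isnan(vv):
        raise SolverError("outlet midpoint fell outside the mesh; bad tags")
    return float(np.hypot(uu, vv))


def detect_vortices(solution: FlowSolution, mesh: Mesh, domain: PlanarDomain,
                    psi: np.ndarray | None = None) -> VortexMetrics:
    """Segment the paired PU recirculation zones from the streamfunction.

    A side vortex is the connected set of nodes inside the PU whose psi lies
    beyond that side's wall value (i.e. past the separatrix), with small
    regions (< 2 local cell diameters across) discarded as noise.  Diameters
    are the axis-aligned extents of the region, in cm.
    """
    if not solution.converged:
        raise SolverError("vortex detection requires a converged solution")
    if domain.spec is None:
        raise SolverError("domain carries no case spec (PU extent unknown)")
    if psi is None:
        psi = compute_streamfunction(solution, mesh)
    g = solution.geom
    spec = domain.spec
    xy = mesh.nodes
    y_bn, y_apex = spec.y_bn * 0.01, spec.y_apex * 0.01

    half = domain.half
    # wall psi per side; on a half mesh the axis plays the left-hand
    # reference role (it is a psi isoline too)
    wall_nodes = np.unique(g.f_nodes[g.boundary[g.b_wall]])
    wx = xy[wall_nodes, 0]
    psi_r = float(np.median(psi[wall_nodes[wx > 0]]))
    if half:
        sym_nodes = np.unique(g.f_nodes[g.boundary[g.b_sym]])
        psi_l = float(np.median(psi[sym_nodes]))
    else:
        psi_l = float(np.median(psi[wall_nodes[wx < 0]]))
    jump = psi_r - psi_l
    if jump == 0.0:
        return VortexMetrics(left=False, right=False)

    in_pu = (xy[:, 1] >= y_apex) & (xy[:, 1] <= y_bn)
    # local cell diameter inside the PU
    cc = g.xc[:, 1]
    pu_cells = (cc >= y_apex) & (cc <= y_bn)
    dloc = float(np.sqrt(2.0 * np.median(g.vol[pu_cells])))

    sides = {}
    pairs = [("right", psi_r, np.sign(jump))]
    if not half:
        pairs.append(("left", psi_l, -np.sign(jump)))
    for side, psi_w, sgn in pairs:
        level = (psi - psi_w) * sgn - PSI_REL_TOL * abs(jump)
        mask = (level > 0) & in_pu & ((xy[:, 0] > 0) if side == "right"
                                      else (xy[:, 0] < 0))
        sides[side] = _largest_region(mesh, mask, dloc, level)
    tdr, ldr = sides["right"]
    if half:
        # the solved field is one symmetric half; the mirror side is
        # identical by construction
        tdl, ldl = tdr, ldr
    else:
        tdl, ldl = sides["left"]
    return VortexMetrics(
        left=tdl is not None, right=tdr is not None,
        td_left=tdl, td_right=tdr, ld_left=ldl, ld_right=ldr)


def _largest_region(mesh: Mesh, mask: np.ndarray, dloc: float,
                    level: np.ndarray | None = None,
                    ) -> tuple[float | None, float | None]:
    """Axis-aligned extents (cm) of the largest masked region.

    Regions narrower than the noise floor are discarded.  When the signed
    ``level`` field defining the region (positive inside) is supplied, the
    extents are refined to sub-cell accuracy by interpolating the zero
    crossing along mesh edges that straddle the separatrix.
    """
    import scipy.sparse as sp
    from scipy.sparse.csgraph import connected_components

    idx = np.where(mask)[0]
    if len(idx) < 3:
        return None, None
    renum = -np.ones(len(mesh.nodes), dtype=np.int64)
    renum[idx] = np.arange(len(idx))
    tri = mesh.triangles
    ed_all = np.vstack([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]])
    keep = mask[ed_all[:, 0]] & mask[ed_all[:, 1]]
    ed = renum[ed_all[keep]]
    adj = sp.coo_matrix((np.ones(len(ed)), (ed[:, 0], ed[:, 1])),
                        shape=(len(idx), len(idx)))
    ncomp, labels = connected_components(adj, directed=False)
    # separatrix-crossing edges: one endpoint inside the mask, one outside
    cross_a = mask[ed_all[:, 0]] & ~mask[ed_all[:, 1]]
    best = None
    for c in range(ncomp):
        inside = idx[labels == c]
        if len(inside) < 3:
            continue
        pts = [mesh.nodes[inside]]
        if level is not None:
            in_comp = np.zeros(len(mesh.nodes), dtype=bool)
            in_comp[inside] = True
            sel = cross_a & in_comp[ed_all[:, 0]]
            if np.any(sel):
                a, b = ed_all[sel, 0], ed_all[sel, 1]
                fa, fb = level[a], level[b]
                t = np.clip(fa / np.maximum(fa - fb, 1e-300), 0.0, 1.0)
                pts.append(mesh.nodes[a]
                           + t[:, None] * (mesh.nodes[b] - mesh.nodes[a]))
        pts = np.vstack(pts)
        ext_x = (pts[:, 0].max() - pts[:, 0].min()) * M_TO_CM
        ext_y = (pts[:, 1].max() - pts[:, 1].min()) * M_TO_CM
        if ext_x < MIN_CELL_DIAMS * dloc * M_TO_CM:
            continue
        if best is None or ext_x * ext_y > best[0] * best[1]:
            best = (ext_x, ext_y)
    if best is None:
        return None, None
    return best


def velocity_profile(solution: FlowSolution, mesh: Mesh, station: float,
                     n: int = 201) -> np.ndarray:
    """Transverse profile of signed axial velocity at height ``station`` (m).

    Returns an (m, 2) array of (x [m], v_axial [m/s]) samples spanning the
    local lumen width; v_axial is positive downstream (downward).  Raises if
    the station does not intersect the fluid domain.
    """
    xy = mesh.nodes
    if station > xy[:, 1].max() or station < xy[:, 1].min():
        raise SolverError(f"station y={station} lies outside the domain")
    fu, fv = _interpolator(solution, mesh)
    xmax = np.abs(xy[:, 0]).max()
    half = mesh.domain is not None and mesh.domain.half
    xs = np.linspace(0.0 if half else -xmax, xmax, n)
    vv = fv(xs, np.full_like(xs, station))
    good = ~vv.mask if np.ma.isMaskedArray(vv) else np.isfinite(vv)
    if not np.any(good):
        raise SolverError(f"station y={station} intersects no elements")
    xs, vv = xs[good], -np.asarray(vv)[good]
    if half:
        # mirror: the axial velocity is even in x on the symmetric solution
        keep = xs > 0
        xs = np.concatenate([-xs[keep][::-1], xs])
        vv = np.concatenate([vv[keep][::-1], vv])
    return np.column_stack([xs, vv])


def summarize_case(spec: GeometrySpec, solution: FlowSolution, mesh: Mesh,
                   domain: PlanarDomain | None = None) -> CaseResult:
    """Assemble the per-case record from a solved flow field."""
    domain = domain if domain is not None else mesh.domain
    rpu1, rpu2 = rpu_ratios(spec)
    base = dict(case_id=spec.case_id, ld_pu=spec.ld_pu, td_bn=spec.td_bn,
                td_pu=spec.td_pu, rpu1=rpu1, rpu2=rpu2,
                converged=solution.converged, n_elements=mesh.n_elements,
                n_iter=solution.n_iter,
                mass_imbalance=solution.mass_imbalance)
    if not solution.converged:
        return CaseResult(**base)
    vm = detect_vortices(solution, mesh, domain)
    return CaseResult(**base, mv_euo=mv_euo(solution, mesh),
                      vortex=vm.present, td_v=vm.td_v, ld_v=vm.ld_v)
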
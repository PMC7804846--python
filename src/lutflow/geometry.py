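"""Parametric 2D geometry of the post-surgical lower urinary tract.

The model idealizes the lower urinary tract at mid-voiding as three stacked
regions sharing a vertical symmetry axis (x = 0, flow in the -y direction):

* the lower half of the bladder — a near-hemispheric cap of fixed transverse
  diameter ``bladder_d`` (10.0 cm) whose top chord is the pressure inlet;
* the prostatic urethra (PU) — the cavity hollowed by transurethral surgery,
  a near-spherical bulge truncated by the bladder-neck (BN) plane above and
  the prostate-apex plane below; its shape is controlled by the three varied
  diameters LD-PU (longitudinal), TD-BN (bladder-neck chord) and TD-PU
  (transverse);
* the rest of the urethra (RU) — a straight 0.6 x 15.7 cm channel ending in
  the external urethral orifice, the pressure outlet.

All lengths in this module are centimetres; the solver converts to SI once
at its boundary.  Anterior bending of the urethra is deliberately ignored:
the model is the maximal coronal profile of the lumen.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Callable, Iterator, Sequence

import numpy as np

__all__ = [
    "GeometryError",
    "GeometrySpec",
    "PlanarDomain",
    "make_case",
    "cats_first",
    "amplification_array",
    "rpu_ratios",
    "pu_wall_profile",
    "assemble_domain",
    "channel_domain",
    "domain_to_csv",
    "domain_to_geo",
    "manifest",
    "LD_PU_GROUPS",
    "TD_BN_SUBGROUPS",
    "TD_PU_VALUES",
]

#: fixed anatomical constants (cm)
BLADDER_D = 10.0
RU_D = 0.6
RU_LEN = 15.7

#: the amplification grid: 3 LD-PU groups x 5 TD-BN subgroups x 14 TD-PU values
LD_PU_GROUPS = {"I": 3.6, "II": 3.8, "III": 4.0}
TD_BN_SUBGROUPS = {"A": 2.6, "B": 2.8, "C": 3.0, "D": 3.2, "E": 3.4}
TD_PU_VALUES = tuple(round(2.0 + 0.2 * i, 1) for i in range(14))  # 2.0 .. 4.6

#: vertex coincidence tolerance for symmetry / closure checks (cm)
SYM_TOL = 1e-9


class GeometryError(ValueError):
    """A geometric constraint was violated; the message names the constraint."""


@dataclass(frozen=True)
class GeometrySpec:
    """One lower-urinary-tract case: the three varied diameters plus constants.

    Lengths in centimetres.  ``ld_pu`` is the distance between the midpoint
    of the BN plane and the midpoint of the prostate-apex plane.
    """

    ld_pu: float
    td_bn: float
    td_pu: float
    bladder_d: float = BLADDER_D
    ru_d: float = RU_D
    ru_len: float = RU_LEN
    case_id: str = ""

    def __post_init__(self) -> None:
        for name in ("ld_pu", "td_bn", "td_pu", "bladder_d", "ru_d", "ru_len"):
            if not getattr(self, name) > 0:
                raise GeometryError(f"{name} must be > 0, got {getattr(self, name)!r}")
        if not self.ru_d < self.td_bn:
            raise GeometryError(
                f"ru_d < td_bn violated: ru_d={self.ru_d} >= td_bn={self.td_bn}"
            )
        if not self.td_pu >= self.ru_d:
            raise GeometryError(
                f"td_pu >= ru_d violated: td_pu={self.td_pu} < ru_d={self.ru_d}"
            )
        if not self.bladder_d > self.td_bn:
            raise GeometryError(
                f"bladder_d > td_bn violated: bladder_d={self.bladder_d} <= td_bn={self.td_bn}"
            )

    # -- characteristic y stations (cm); inlet chord at y = 0, flow downward --
    @property
    def y_inlet(self) -> float:
        return 0.0

    @property
    def y_bn(self) -> float:
        return -self.bladder_d / 2.0

    @property
    def y_apex(self) -> float:
        return self.y_bn - self.ld_pu

    @property
    def y_outlet(self) -> float:
        return self.y_apex - self.ru_len

    @property
    def total_height(self) -> float:
        return self.bladder_d / 2.0 + self.ld_pu + self.ru_len


def make_case(ld_pu: float, td_bn: float, td_pu: float, case_id: str = "") -> GeometrySpec:
    """Build a validated case spec from the three varied diameters (cm)."""
    return GeometrySpec(ld_pu=float(ld_pu), td_bn=float(td_bn), td_pu=float(td_pu),
                        case_id=case_id)


def cats_first() -> GeometrySpec:
    """The index case: LD-PU 3.8 cm, TD-BN 3.0 cm, TD-PU 4.2 cm."""
    return make_case(3.8, 3.0, 4.2, case_id="II-C-12")


def amplification_array() -> list[GeometrySpec]:
    """Enumerate the full 3 x 5 x 14 = 210 case array, in deterministic order.

    Groups (LD-PU): I 3.6, II 3.8, III 4.0 cm; subgroups (TD-BN): A 2.6 ..
    E 3.4 cm; within each subgroup TD-PU runs 2.0 .. 4.6 cm every 0.2 cm.
    """
    specs = []
    for g, ld in LD_PU_GROUPS.items():
        for s, bn in TD_BN_SUBGROUPS.items():
            for i, td in enumerate(TD_PU_VALUES, start=1):
                specs.append(make_case(ld, bn, td, case_id=f"{g}-{s}-{i:02d}"))
    return specs


def rpu_ratios(spec: GeometrySpec) -> tuple[float, float]:
    """The two diameter ratios of the PU.

    RPU-1 = TD-PU / TD-BN (dimensionless); RPU-2 = RPU-1 / LD-PU with LD-PU
    expressed in millimetres (per-mm), which puts RPU-2 on the conventional
    0.02-0.04 scale.
    """
    rpu1 = spec.td_pu / spec.td_bn
    rpu2 = rpu1 / (spec.ld_pu * 10.0)
    return rpu1, rpu2


# ---------------------------------------------------------------------------
# wall-curve construction
# ---------------------------------------------------------------------------

def _pu_bulge_coefficient(spec: GeometrySpec) -> float:
    """Bulge coefficient K of the parabolic PU wall x(s) = r_a + D*s + K*s*(1-s).

    s runs 0 at the apex plane to 1 at the BN plane; r_a = ru_d/2,
    r_b = td_bn/2, D = r_b - r_a.  The third width constraint is applied at
    the parabola's vertex (widest station) when TD-PU >= TD-BN, and at the
    PU mid-height when TD-PU < TD-BN (the tapering, trapezoid-like shapes).
    """
    r_a = spec.ru_d / 2.0
    r_b = spec.td_bn / 2.0
    r_p = spec.td_pu / 2.0
    delta = r_b - r_a
    h = r_p - r_a
    if spec.td_pu >= spec.td_bn:
        disc = h * (h - delta)
        if disc < -1e-12:
            raise GeometryError(
                "no parabolic wall satisfies max-width constraint: "
                f"td_pu={spec.td_pu} < td_bn={spec.td_bn}"
            )
        k = (2.0 * h - delta) + 2.0 * math.sqrt(max(disc, 0.0))
    else:
        k = 4.0 * (h - delta / 2.0)
    return k


def _pu_half_width(spec: GeometrySpec, s: np.ndarray) -> np.ndarray:
    r_a = spec.ru_d / 2.0
    delta = spec.td_bn / 2.0 - r_a
    k = _pu_bulge_coefficient(spec)
    return r_a + delta * s + k * s * (1.0 - s)


def _bladder_half_width(spec: GeometrySpec, y: np.ndarray) -> np.ndarray:
    # vertically stretched circular arc: vertical tangent at the equator
    # (y = 0), half-width td_bn/2 exactly at the BN plane (y = -bladder_d/2);
    # the arc meets the PU wall at a corner (the zero-thickness neck lip)
    y = np.asarray(y, dtype=float)
    r = spec.bladder_d / 2.0
    r_bn = spec.td_bn / 2.0
    ry = r / math.sqrt(1.0 - (r_bn / r) ** 2)
    return r * np.sqrt(np.clip(1.0 - (y / ry) ** 2, 0.0, None))


def half_width(spec: GeometrySpec, y: np.ndarray) -> np.ndarray:
    """Lumen half-width (cm) as a single-valued function of height y (cm)."""
    y = np.asarray(y, dtype=float)
    out = np.empty_like(y)
    in_bladder = y >= spec.y_bn
    in_pu = (y < spec.y_bn) & (y >= spec.y_apex)
    in_ru = y < spec.y_apex
    out[in_bladder] = _bladder_half_width(spec, y[in_bladder])
    s = (y[in_pu] - spec.y_apex) / spec.ld_pu
    out[in_pu] = _pu_half_width(spec, s)
    out[in_ru] = spec.ru_d / 2.0
    return out


def pu_wall_profile(spec: GeometrySpec, n: int = 101) -> tuple[np.ndarray, np.ndarray]:
    """Left and right PU wall curves, apex plane to BN plane.

    Returns two (n, 2) arrays of (x, y) points in cm; the left curve is the
    exact mirror of the right.  Both are single-valued in y.
    """
    if n < 2:
        raise GeometryError("need at least 2 sample points")
    s = np.linspace(0.0, 1.0, n)
    x = _pu_half_width(spec, s)
    if np.any(x <= 0.0):
        raise GeometryError("PU wall curve crosses the symmetry axis; "
                            "width constraints are unsatisfiable")
    y = spec.y_apex + s * spec.ld_pu
    right = np.column_stack([x, y])
    left = np.column_stack([-x, y])
    return left, right


# ---------------------------------------------------------------------------
# domain assembly
# ---------------------------------------------------------------------------

INLET, OUTLET, WALL, SYMMETRY = "inlet", "outlet", "wall", "symmetry"


@dataclass(frozen=True)
class PlanarDomain:
    """Closed, boundary-tagged outline of one case (lengths in cm).

    ``points`` is an ordered, counter-clockwise, non-repeating polyline; edge
    i joins ``points[i]`` to ``points[(i+1) % n]`` and carries
    ``edge_tags[i]``.  Exactly one contiguous inlet run (top chord) and one
    outlet run (bottom chord); mirror-symmetric about ``axis_x``.

    ``width_fn`` gives the analytic lumen half-width at any height and
    ``y_sections`` the region-boundary heights (inlet, BN, apex, outlet);
    the mesher uses these rather than re-fitting the polyline.
    """

    points: np.ndarray
    edge_tags: tuple[str, ...]
    axis_x: float
    spec: GeometrySpec | None = None
    width_fn: Callable[[np.ndarray], np.ndarray] | None = field(default=None, repr=False)
    y_sections: tuple[float, ...] = ()
    #: right-half outline with a symmetry edge along the axis instead of the
    #: mirrored left wall (production solves exploit the mirror symmetry)
    half: bool = False

    @property
    def n_edges(self) -> int:
        return len(self.points)

    def edges(self) -> Iterator[tuple[np.ndarray, np.ndarray, str]]:
        pts = self.points
        n = len(pts)
        for i in range(n):
            yield pts[i], pts[(i + 1) % n], self.edge_tags[i]

    def tag_length(self, tag: str) -> float:
        total = 0.0
        for a, b, t in self.edges():
            if t == tag:
                total += float(np.hypot(*(b - a)))
        return total

    def area(self) -> float:
        x, y = self.points[:, 0], self.points[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    def contains(self, xy: np.ndarray) -> np.ndarray:
        from matplotlib.path import Path

        return Path(self.points).contains_points(np.atleast_2d(xy))

    def is_simple(self) -> bool:
        from shapely.geometry import Polygon

        return Polygon(self.points).is_valid

    def check_symmetry(self, tol: float = SYM_TOL) -> bool:
        if self.half:
            return True    # symmetric by construction
        mirrored = self.points.copy()
        mirrored[:, 0] = 2.0 * self.axis_x - mirrored[:, 0]
        # mirrored point set must coincide with the original point set
        orig = {tuple(np.round(p, 12)) for p in self.points}
        mirr = {tuple(np.round(p, 12)) for p in mirrored}
        if len(orig) != len(mirr):
            return False
        pts = self.points
        for p in mirrored:
            d = np.min(np.hypot(pts[:, 0] - p[0], pts[:, 1] - p[1]))
            if d > tol:
                return False
        return True


def _arc_points(spec: GeometrySpec, y_hi: float, y_lo: float, n: int,
                region: str) -> np.ndarray:
    """Right-wall sample points from y_hi down to y_lo (excludes y_hi)."""
    y = np.linspace(y_hi, y_lo, n + 1)[1:]
    x = half_width(spec, y)
    return np.column_stack([x, y])


def assemble_domain(spec: GeometrySpec, resolution: int = 64,
                    half: bool = False) -> PlanarDomain:
    """Closed boundary-tagged outline of one case.

    ``resolution`` controls polyline density per curved region.  The outline
    runs counter-clockwise: inlet chord right-to-left, left wall downward,
    outlet chord left-to-right, right wall upward.  The BN meets the PU at a
    re-entrant corner (the zero-thickness bladder neck).

    With ``half=True`` only the right half is assembled and the axis becomes
    a symmetry edge; production solves use the half outline (geometry and
    boundary conditions are mirror-symmetric), the full outline serves
    exports and full-field cross-checks.
    """
    n_bl = resolution
    n_pu = resolution
    n_ru = max(8, resolution // 4)

    right = np.vstack([
        np.array([[spec.bladder_d / 2.0, 0.0]]),
        _arc_points(spec, 0.0, spec.y_bn, n_bl, "bladder"),
        _arc_points(spec, spec.y_bn, spec.y_apex, n_pu, "pu"),
        _arc_points(spec, spec.y_apex, spec.y_outlet, n_ru, "ru"),
    ])

    pts: list[np.ndarray] = []
    tags: list[str] = []
    if half:
        # CCW: inlet (right->axis), axis downward, outlet (axis->right wall),
        # right wall upward
        pts.append(right[0])
        tags.append(INLET)
        pts.append(np.array([0.0, 0.0]))
        tags.append(SYMMETRY)
        pts.append(np.array([0.0, spec.y_outlet]))
        tags.append(OUTLET)
        for p in right[::-1][:-1]:
            pts.append(p)
            tags.append(WALL)
    else:
        left = right.copy()
        left[:, 0] = -left[:, 0]
        # CCW: inlet (right->left), left wall (top->bottom), outlet
        # (left->right), right wall (bottom->top); corner points shared
        pts.append(right[0])           # (+bladder_d/2, 0)
        tags.append(INLET)             # edge to left end of inlet
        for p in left[:-1]:
            pts.append(p)
            tags.append(WALL)
        pts.append(left[-1])           # (-ru_d/2, y_outlet)
        tags.append(OUTLET)
        for p in right[::-1][:-1]:
            pts.append(p)
            tags.append(WALL)

    points = np.array(pts)
    domain = PlanarDomain(
        points=points,
        edge_tags=tuple(tags),
        axis_x=0.0,
        spec=spec,
        width_fn=lambda y: half_width(spec, y),
        y_sections=(spec.y_outlet, spec.y_apex, spec.y_bn, 0.0),
        half=half,
    )
    if not domain.is_simple():
        raise GeometryError(f"assembled outline self-intersects for {spec}")
    return domain


def channel_domain(width: float, length: float) -> PlanarDomain:
    """A plain vertical channel (width x length, cm): inlet top, outlet bottom.

    Validation geometry: pressure-driven flow in this domain has the
    plane-Poiseuille closed form in the laminar limit.
    """
    w = width / 2.0
    points = np.array([
        [w, 0.0], [-w, 0.0], [-w, -length], [w, -length],
    ])
    tags = (INLET, WALL, OUTLET, WALL)
    return PlanarDomain(
        points=points, edge_tags=tags, axis_x=0.0, spec=None,
        width_fn=lambda y: np.full_like(np.asarray(y, dtype=float), w),
        y_sections=(-length, 0.0),
    )


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def domain_to_csv(domain: PlanarDomain) -> str:
    """Closed polyline as CSV text: x_cm, y_cm, tag (tag of the edge leaving
    the point)."""
    buf = io.StringIO()
    buf.write("# lengths in cm\n")
    buf.write("x_cm,y_cm,tag\n")
    for p, tag in zip(domain.points, domain.edge_tags):
        buf.write(f"{p[0]:.9g},{p[1]:.9g},{tag}\n")
    return buf.getvalue()


def domain_to_geo(domain: PlanarDomain) -> str:
    """Gmsh .geo-style loop description of the outline (cm units)."""
    lines = ["// lengths in cm"]
    n = len(domain.points)
    for i, p in enumerate(domain.points, start=1):
        lines.append(f"Point({i}) = {{{p[0]:.9g}, {p[1]:.9g}, 0}};")
    for i in range(1, n + 1):
        j = i % n + 1
        lines.append(f"Line({i}) = {{{i}, {j}}};")
    loop = ", ".join(str(i) for i in range(1, n + 1))
    lines.append(f"Curve Loop(1) = {{{loop}}};")
    lines.append("Plane Surface(1) = {1};")
    for tag in (INLET, OUTLET, WALL):
        ids = [str(i + 1) for i, t in enumerate(domain.edge_tags) if t == tag]
        lines.append(f'Physical Curve("{tag}") = {{{", ".join(ids)}}};')
    return "\n".join(lines) + "\n"


def manifest(specs: Sequence[GeometrySpec]) -> "pandas.DataFrame":  # noqa: F821
    """Case manifest: id, the three diameters and the two RPU ratios."""
    import pandas as pd

    rows = []
    for s in specs:
        r1, r2 = rpu_ratios(s)
        rows.append({"case_id": s.case_id, "ld_pu_cm": s.ld_pu,
                     "td_bn_cm": s.td_bn, "td_pu_cm": s.td_pu,
                     "rpu1": r1, "rpu2": r2})
    return pd.DataFrame(rows)
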
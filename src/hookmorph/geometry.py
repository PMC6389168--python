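"""Point-to-point morphometry of a digitized haptoral hook outline.

The hook of a diplozoid central-hook complex is a curved sclerite with a
straight shaft, a curved blade and a recurved point; the straight handle
articulates at the shaft base.  Given a labeled outline (inner and outer
edge polylines running from the point tip to the articulation base, plus
the articulation-base landmark B), this module derives the construction
points used by the vector/angle measurement scheme — perpendicular feet,
edge zeniths, line/edge intercepts — and from them the 13 hook variables;
the handle length (HNL) comes from the two handle landmarks.

Definitions implemented here (T = point tip, B = articulation base):

* AD  — |T − B|, the aperture distance.
* Z_out — zenith of the outer edge relative to the AD line (distal window);
  F_AD is its perpendicular foot on the AD line; the PL line runs through
  F_AD and Z_out and PL = |F_AD − Z_out|.
* P_in — intercept of the PL segment (F_AD→Z_out) with the inner edge,
  taking the crossing adjacent to Z_out so that DSW = |P_in − Z_out| is
  the width of the sclerite at that section; ISL = |P_in − B|.
* H_heel — zenith of the outer edge towards the heel (proximal window);
  PSW = |B − H_heel|, OSL = |Z_out − H_heel|.
* The chord T–Z_out bounds the blade: ICL / OCL are the perpendicular
  distances of the inner-/outer-blade zeniths to that chord, where the
  blade sections run from the tip to the PL intercept on each edge
  (P_in on the inner edge, Z_out itself on the outer edge), and
  DPL = |T − Z_out|.
* PCA — angle at the vertex Z_out between the PL segment (ray to F_AD)
  and the chord (ray to T); OAA — angle at Z_out between rays to H_heel
  and T; IAA — angle at P_in between rays to B and T.  Angles in degrees.
* HL  — extent of the whole outline projected on the shaft axis (a
  total-least-squares line through the flagged straight shaft section of
  the inner edge).

All routines operate on 2-D Cartesian coordinates in micrometres (after
``units_scale``); no image-axis flipping is performed — callers digitizing
from images with a downward y-axis must flip beforehand.  Zenith searches
run on a densified resampling of the edge (default step 0.02 um) and break
ties by the smallest arc length from the tip.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from shapely.geometry import LineString, MultiPoint, Point

from .errors import DegenerateInputError, GeometryError
from .variables import ANGLE_VARIABLES, VARIABLE_NAMES

__all__ = [
    "HookOutline",
    "DerivedLandmarks",
    "MeasurementSet",
    "GeometryOptions",
    "fit_shaft_axis",
    "find_zenith",
    "derive_landmarks",
    "measure_hook",
    "measure_handle",
]

#: Default densification step for zenith searches, in micrometres.
DEFAULT_DENSIFY_STEP = 0.02

#: Default projection windows (fractions of the B→T span) for the distal
#: outer zenith and the proximal heel zenith.
DEFAULT_DISTAL_WINDOW = (0.4, 1.0)
DEFAULT_PROXIMAL_WINDOW = (0.0, 0.4)

_EPS = 1e-12


@dataclass(frozen=True)
class GeometryOptions:
    """Tunable constants of the measurement engine."""

    densify_step: float = DEFAULT_DENSIFY_STEP
    distal_window: tuple[float, float] = DEFAULT_DISTAL_WINDOW
    proximal_window: tuple[float, float] = DEFAULT_PROXIMAL_WINDOW


@dataclass
class HookOutline:
    """Labeled, ordered digitized outline of one hook.

    ``inner_edge`` and ``outer_edge`` run from the point tip to the
    articulation end and share their first vertex (the tip T).
    ``articulation_base`` is the landmark B at the centre of the base of
    the hook–handle articulation; it need not lie on either edge.
    ``straight_range`` flags the index interval (start, stop) of
    ``inner_edge`` vertices forming the straight shaft section; when
    ``None`` the proximal 40% of the inner edge is used.
    """

    specimen_id: str
    inner_edge: np.ndarray
    outer_edge: np.ndarray
    articulation_base: np.ndarray
    straight_range: tuple[int, int] | None = None
    handle: tuple[np.ndarray, np.ndarray] | None = None
    units_scale: float = 1.0

    def __post_init__(self) -> None:
        self.inner_edge = np.asarray(self.inner_edge, dtype=float)
        self.outer_edge = np.asarray(self.outer_edge, dtype=float)
        self.articulation_base = np.asarray(self.articulation_base, dtype=float)
        if self.handle is not None:
            self.handle = (
                np.asarray(self.handle[0], dtype=float),
                np.asarray(self.handle[1], dtype=float),
            )
        self.validate()

    @property
    def tip(self) -> np.ndarray:
        return self.inner_edge[0]

    def validate(self) -> None:
        for name, edge in (("inner_edge", self.inner_edge), ("outer_edge", self.outer_edge)):
            if edge.ndim != 2 or edge.shape[1] != 2 or edge.shape[0] < 2:
                raise DegenerateInputError(f"{name} must be an (n>=2, 2) polyline")
        if self.units_scale <= 0:
            raise DegenerateInputError("units_scale must be positive")
        if not np.allclose(self.inner_edge[0], self.outer_edge[0], atol=1e-6):
            raise DegenerateInputError(
                "inner and outer edges must share the tip as their first vertex"
            )
        if self.straight_range is not None:
            lo, hi = self.straight_range
            if not (0 <= lo < hi <= len(self.inner_edge)):
                raise DegenerateInputError("straight_range outside inner_edge indices")

    def effective_straight_range(self) -> tuple[int, int]:
        if self.straight_range is not None:
            return self.straight_range
        n = len(self.inner_edge)
        return (int(np.floor(0.6 * n)), n)  # proximal 40% (edges run tip->base)

    def to_um(self) -> "HookOutline":
        """Return a copy with coordinates converted to micrometres."""
        s = self.units_scale
        if s == 1.0:
            return self
        handle = None
        if self.handle is not None:
            handle = (self.handle[0] * s, self.handle[1] * s)
        return replace(
            self,
            inner_edge=self.inner_edge * s,
            outer_edge=self.outer_edge * s,
            articulation_base=self.articulation_base * s,
            handle=handle,
            units_scale=1.0,
        )

    def transformed(self, rotation_deg: float = 0.0, translation=(0.0, 0.0),
                    reflect: bool = False) -> "HookOutline":
        """Rigidly transformed copy (rotation about the origin, then shift)."""
        th = np.deg2rad(rotation_deg)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        if reflect:
            R = R @ np.diag([1.0, -1.0])
        t = np.asarray(translation, dtype=float)

        def f(pts):
            return np.atleast_2d(pts) @ R.T + t

        handle = None
        if self.handle is not None:
            handle = (f(self.handle[0])[0], f(self.handle[1])[0])
        return replace(
            self,
            inner_edge=f(self.inner_edge),
            outer_edge=f(self.outer_edge),
            articulation_base=f(self.articulation_base)[0],
            handle=handle,
        )


@dataclass
class DerivedLandmarks:
    """Construction points derived from a hook outline (all in um)."""

    tip: np.ndarray
    base: np.ndarray
    Z_out: np.ndarray
    F_AD: np.ndarray
    P_in: np.ndarray
    H_heel: np.ndarray
    Z_inner_blade: np.ndarray
    Z_outer_blade: np.ndarray
    shaft_axis_point: np.ndarray
    shaft_axis_direction: np.ndarray
    Z_out_arclength: float = field(default=float("nan"))
    P_in_arclength: float = field(default=float("nan"))

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            "tip": self.tip,
            "base": self.base,
            "Z_out": self.Z_out,
            "F_AD": self.F_AD,
            "P_in": self.P_in,
            "H_heel": self.H_heel,
            "Z_inner_blade": self.Z_inner_blade,
            "Z_outer_blade": self.Z_outer_blade,
        }


@dataclass
class MeasurementSet:
    """The named morphometric values for one specimen.

    Lengths in micrometres, angles (PCA, IAA, OAA) in degrees.  HNL is
    absent when the specimen carries no handle landmarks.
    """

    values: dict[str, float]
    specimen_id: str = ""

    def __post_init__(self) -> None:
        unknown = set(self.values) - set(VARIABLE_NAMES)
        if unknown:
            raise ValueError(f"unknown measurement names: {sorted(unknown)}")

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def __contains__(self, name: str) -> bool:
        return name in self.values

    def as_row(self) -> dict[str, float]:
        """Values in canonical column order (missing variables as NaN)."""
        return {v: self.values.get(v, float("nan")) for v in VARIABLE_NAMES}

    def validate(self) -> None:
        for name, value in self.values.items():
            if name in ANGLE_VARIABLES:
                if not (0.0 < value < 180.0):
                    raise GeometryError(f"{name}={value!r} outside (0, 180) degrees")
            elif value < 0:
                raise GeometryError(f"{name}={value!r} negative length")


# ---------------------------------------------------------------------------
# polyline helpers


def _arclengths(pts: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def densify_polyline(pts: np.ndarray, step: float) -> tuple[np.ndarray, np.ndarray]:
    """Resample a polyline at arc-length spacing <= ``step``.

    Original vertices are retained, so every returned point lies exactly on
    the input polyline.  Returns (points, arclengths).
    """
    pts = np.asarray(pts, dtype=float)
    s = _arclengths(pts)
    total = s[-1]
    if total <= _EPS:
        return pts, s
    n = max(2, int(np.ceil(total / step)) + 1)
    grid = np.linspace(0.0, total, n)
    all_s = np.union1d(grid, s)
    x = np.interp(all_s, s, pts[:, 0])
    y = np.interp(all_s, s, pts[:, 1])
    return np.column_stack([x, y]), all_s


def _perp_distance(pts: np.ndarray, a: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Unsigned perpendicular distance of points to the line through a with unit direction u."""
    d = np.atleast_2d(pts) - a
    return np.abs(d[:, 0] * u[1] - d[:, 1] * u[0])


def _angle_deg(v1: np.ndarray, v2: np.ndarray) -> float:
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 <= _EPS or n2 <= _EPS:
        raise DegenerateInputError("coincident vertices define no angle")
    c = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


# ---------------------------------------------------------------------------
# operations


def fit_shaft_axis(outline: HookOutline) -> tuple[np.ndarray, np.ndarray]:
    """Total-least-squares line through the flagged straight shaft section.

    Returns ``(point, direction)`` with the unit direction oriented from the
    articulation end towards the tip.  The fitted line is the principal
    eigenvector of the vertex scatter about its centroid.
    """
    outline = outline.to_um()
    lo, hi = outline.effective_straight_range()
    pts = outline.inner_edge[lo:hi]
    if len(pts) < 2:
        raise DegenerateInputError("straight section needs at least 2 vertices")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    scatter = centered.T @ centered
    if np.trace(scatter) <= _EPS:
        raise DegenerateInputError("straight-section vertices are coincident")
    evals, evecs = np.linalg.eigh(scatter)
    direction = evecs[:, np.argmax(evals)]
    # edges run tip -> base, so first flagged vertex is the tipward end
    tipward = pts[0] - pts[-1]
    if np.dot(direction, tipward) < 0:
        direction = -direction
    return centroid, direction


@dataclass
class ZenithResult:
    point: np.ndarray
    distance: float
    arclength: float
    t: float  # projection parameter on the reference segment


def find_zenith(edge: np.ndarray, line_a, line_b, region: tuple[float, float] = (0.0, 1.0),
                step: float = DEFAULT_DENSIFY_STEP) -> ZenithResult:
    """Edge point at maximal perpendicular distance to the reference line.

    The reference line is the segment ``line_a``→``line_b``; ``region``
    restricts candidates to projection parameters (0 at ``line_a``, 1 at
    ``line_b``) inside the given interval, with the exact boundary-crossing
    points included.  The edge is densified at arc-length step ``step`` and
    ties are broken by the smallest arc length from the edge start (the tip).
    """
    a = np.asarray(line_a, dtype=float)
    b = np.asarray(line_b, dtype=float)
    L = np.linalg.norm(b - a)
    if L <= _EPS:
        raise DegenerateInputError("reference line endpoints coincide")
    lo, hi = region
    if not lo < hi:
        raise ValueError("empty zenith search region")
    u = (b - a) / L

    pts, s = densify_polyline(np.asarray(edge, dtype=float), step)
    t = ((pts - a) @ u) / L

    # exact crossings of the region boundaries
    extra_pts, extra_s, extra_t = [], [], []
    for v in (lo, hi):
        dt = t - v
        cross = np.nonzero(dt[:-1] * dt[1:] < 0)[0]
        for i in cross:
            alpha = dt[i] / (dt[i] - dt[i + 1])
            extra_pts.append(pts[i] + alpha * (pts[i + 1] - pts[i]))
            extra_s.append(s[i] + alpha * (s[i + 1] - s[i]))
            extra_t.append(v)
    if extra_pts:
        pts = np.vstack([pts, extra_pts])
        s = np.concatenate([s, extra_s])
        t = np.concatenate([t, extra_t])

    mask = (t >= lo - 1e-9) & (t <= hi + 1e-9)
    if not mask.any():
        raise GeometryError("no edge points project into the zenith search region")
    pts, s, t = pts[mask], s[mask], t[mask]
    order = np.argsort(s, kind="stable")
    pts, s, t = pts[order], s[order], t[order]

    dist = _perp_distance(pts, a, u)
    idx = int(np.argmax(dist))  # first (smallest arc length) on exact ties
    return ZenithResult(point=pts[idx], distance=float(dist[idx]),
                        arclength=float(s[idx]), t=float(t[idx]))


def _line_polyline_intersections(p0: np.ndarray, direction: np.ndarray,
                                 polyline: np.ndarray) -> list[np.ndarray]:
    """Intersections of the infinite line through p0 with a polyline (shapely)."""
    d = direction / np.linalg.norm(direction)
    span = np.ptp(polyline, axis=0).sum() + np.linalg.norm(p0 - polyline[0]) + 1.0
    seg = LineString([p0 - 2 * span * d, p0 + 2 * span * d])
    inter = seg.intersection(LineString(polyline))
    if inter.is_empty:
        return []
    if isinstance(inter, Point):
        geoms = [inter]
    elif isinstance(inter, MultiPoint):
        geoms = list(inter.geoms)
    else:  # collections / collinear overlaps: take representative vertices
        geoms = []
        for g in getattr(inter, "geoms", [inter]):
            if isinstance(g, Point):
                geoms.append(g)
            else:
                geoms.extend(Point(c) for c in g.coords)
    return [np.array([g.x, g.y]) for g in geoms]


def derive_landmarks(outline: HookOutline,
                     options: GeometryOptions = GeometryOptions()) -> DerivedLandmarks:
    """Compute every construction point of the measurement scheme.

    Raises :class:`GeometryError` for degenerate hooks (no blade curvature,
    PL line missing the inner edge).
    """
    outline = outline.to_um()
    T = outline.tip
    B = outline.articulation_base
    AD_len = np.linalg.norm(T - B)
    if AD_len <= _EPS:
        raise GeometryError("tip and articulation base coincide")
    step = options.densify_step

    z_out = find_zenith(outline.outer_edge, B, T, options.distal_window, step)
    if z_out.distance <= max(1e-6, 1e-4 * AD_len) or np.linalg.norm(z_out.point - T) <= _EPS:
        raise GeometryError("no blade curvature: outer zenith degenerate (straight hook)")
    Z_out = z_out.point

    u = (T - B) / AD_len
    F_AD = B + u * np.dot(Z_out - B, u)

    # P_in: crossing of the PL segment with the inner edge adjacent to
    # Z_out (the hook width at that section).  In strongly recurved hooks
    # the point section also crosses the PL line; those crossings lie on
    # the F_AD side and are not the DSW section.
    pl_len = np.linalg.norm(Z_out - F_AD)
    pl_dir = (Z_out - F_AD) / pl_len
    hits = _line_polyline_intersections(F_AD, pl_dir, outline.inner_edge)
    hits = [p for p in hits
            if -1e-9 <= np.dot(p - F_AD, pl_dir) <= pl_len + 1e-9]
    if not hits:
        raise GeometryError("PL segment does not intersect the inner edge")
    P_in = max(hits, key=lambda p: np.dot(p - F_AD, pl_dir))
    P_in_s = float(LineString(outline.inner_edge).project(Point(P_in)))

    h_heel = find_zenith(outline.outer_edge, B, T, options.proximal_window, step)
    H_heel = h_heel.point

    # blade zeniths relative to the chord T - Z_out; each edge's blade
    # section runs from the tip to the PL intercept on that edge
    inner_dense, inner_s = densify_polyline(outline.inner_edge, step)
    inner_blade = inner_dense[inner_s <= P_in_s + 1e-9]
    inner_blade = np.vstack([inner_blade, P_in])
    if len(inner_blade) < 2:
        raise GeometryError("inner blade section is empty")
    z_inner = find_zenith(inner_blade, T, Z_out, (0.0, 1.0), step)

    outer_dense, outer_s = densify_polyline(outline.outer_edge, step)
    outer_blade = outer_dense[outer_s <= z_out.arclength + 1e-9]
    if len(outer_blade) < 2:
        raise GeometryError("outer blade section is empty")
    z_outer = find_zenith(outer_blade, T, Z_out, (0.0, 1.0), step)

    axis_point, axis_dir = fit_shaft_axis(outline)
    return DerivedLandmarks(
        tip=T, base=B, Z_out=Z_out, F_AD=F_AD, P_in=P_in, H_heel=H_heel,
        Z_inner_blade=z_inner.point, Z_outer_blade=z_outer.point,
        shaft_axis_point=axis_point, shaft_axis_direction=axis_dir,
        Z_out_arclength=z_out.arclength, P_in_arclength=P_in_s,
    )


def measure_hook(outline: HookOutline,
                 options: GeometryOptions = GeometryOptions(),
                 landmarks: DerivedLandmarks | None = None) -> MeasurementSet:
    """All hook measurements for one specimen (plus HNL when a handle is present)."""
    outline = outline.to_um()
    lm = landmarks if landmarks is not None else derive_landmarks(outline, options)
    T, B = lm.tip, lm.base
    Z, F, P, H = lm.Z_out, lm.F_AD, lm.P_in, lm.H_heel

    chord_u = (Z - T) / np.linalg.norm(Z - T)
    values = {
        "AD": float(np.linalg.norm(T - B)),
        "PSW": float(np.linalg.norm(B - H)),
        "PL": float(np.linalg.norm(F - Z)),
        "DSW": float(np.linalg.norm(P - Z)),
        "ICL": float(_perp_distance(lm.Z_inner_blade, T, chord_u)[0]),
        "OCL": float(_perp_distance(lm.Z_outer_blade, T, chord_u)[0]),
        "DPL": float(np.linalg.norm(T - Z)),
        "ISL": float(np.linalg.norm(P - B)),
        "OSL": float(np.linalg.norm(Z - H)),
        "PCA": _angle_deg(F - Z, T - Z),  # at vertex Z_out: rays to F_AD and to T
        "OAA": _angle_deg(H - Z, T - Z),
        "IAA": _angle_deg(B - P, T - P),
    }
    proj = np.concatenate([outline.inner_edge, outline.outer_edge]) @ lm.shaft_axis_direction
    values["HL"] = float(proj.max() - proj.min())
    if outline.handle is not None:
        values["HNL"] = measure_handle(*outline.handle)
    return MeasurementSet(values=values, specimen_id=outline.specimen_id)


def measure_handle(handle_tip, handle_base) -> float:
    """Handle length: Euclidean distance from handle tip to handle base (um)."""
    tip = np.asarray(handle_tip, dtype=float)
    base = np.asarray(handle_base, dtype=float)
    d = float(np.linalg.norm(tip - base))
    if d <= _EPS:
        warnings.warn("handle tip and base coincide; HNL reported as 0", stacklevel=2)
        return 0.0
    return d
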
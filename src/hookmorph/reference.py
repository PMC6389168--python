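"""Brute-force reference implementation of the hook measurements.

This module recomputes every derived landmark and measurement by direct
exhaustive search over a densely sampled outline: zeniths are argmaxes over
the sampled vertices (with exact window-boundary points inserted), line/edge
intercepts come from solving each segment's 2x2 linear system, and the shaft
axis from an SVD.  It shares no code with :mod:`hookmorph.geometry` and is
used as the independent ground truth for the parametric shape fixtures and
in the test suite.  It is slower and offers no error reporting beyond basic
degeneracy checks — use :func:`hookmorph.geometry.measure_hook` for real work.
"""

from __future__ import annotations

import numpy as np

from .errors import GeometryError
from .geometry import DerivedLandmarks, HookOutline, MeasurementSet

__all__ = ["reference_landmarks", "reference_measurements"]


def _resample(pts: np.ndarray, step: float) -> tuple[np.ndarray, np.ndarray]:
    """Dense arc-length resampling keeping the original vertices."""
    pts = np.asarray(pts, dtype=float)
    seg = np.sqrt(((pts[1:] - pts[:-1]) ** 2).sum(axis=1))
    s = np.concatenate([[0.0], seg.cumsum()])
    if s[-1] == 0.0:
        return pts, s
    dense_s = [s[0]]
    for i in range(len(seg)):
        if seg[i] == 0.0:
            continue
        k = int(np.ceil(seg[i] / step))
        for j in range(1, k + 1):
            dense_s.append(s[i] + seg[i] * j / k)
    dense_s = np.array(dense_s)
    x = np.interp(dense_s, s, pts[:, 0])
    y = np.interp(dense_s, s, pts[:, 1])
    return np.column_stack([x, y]), dense_s


def _window(pts, s, a, b, lo, hi):
    """Vertices whose projection parameter on a->b lies in [lo, hi], with the
    exact boundary crossings appended, ordered by arc length."""
    u = (b - a) / np.linalg.norm(b - a)
    t = ((pts - a) @ u) / np.linalg.norm(b - a)
    keep_p, keep_s = [], []
    for i in range(len(pts)):
        if lo - 1e-9 <= t[i] <= hi + 1e-9:
            keep_p.append(pts[i])
            keep_s.append(s[i])
        if i + 1 < len(pts):
            for v in (lo, hi):
                if (t[i] - v) * (t[i + 1] - v) < 0:
                    al = (v - t[i]) / (t[i + 1] - t[i])
                    keep_p.append(pts[i] + al * (pts[i + 1] - pts[i]))
                    keep_s.append(s[i] + al * (s[i + 1] - s[i]))
    if not keep_p:
        raise GeometryError("reference zenith window is empty")
    keep_p = np.array(keep_p)
    keep_s = np.array(keep_s)
    order = np.argsort(keep_s, kind="stable")
    return keep_p[order], keep_s[order]


def _zenith(pts, s, a, b, lo, hi):
    """Exhaustive argmax of perpendicular distance inside a projection window."""
    wp, ws = _window(pts, s, a, b, lo, hi)
    u = (b - a) / np.linalg.norm(b - a)
    d = np.abs((wp[:, 0] - a[0]) * u[1] - (wp[:, 1] - a[1]) * u[0])
    best = 0
    for i in range(1, len(wp)):
        if d[i] > d[best]:
            best = i
    return wp[best], float(ws[best]), float(d[best])


def _line_hits(p0, direction, pts, s):
    """Intersections of an infinite line with a polyline, by segment solve.

    Returns ``[(point, arclength), ...]``.
    """
    d = direction / np.linalg.norm(direction)
    hits = []
    for i in range(len(pts) - 1):
        e = pts[i + 1] - pts[i]
        c1 = d[0] * e[1] - d[1] * e[0]
        w = pts[i] - p0
        c0 = d[0] * w[1] - d[1] * w[0]
        if abs(c1) < 1e-14:
            if abs(c0) < 1e-12:  # collinear segment: endpoints are hits
                hits.append((pts[i].copy(), float(s[i])))
                hits.append((pts[i + 1].copy(), float(s[i + 1])))
            continue
        beta = -c0 / c1
        if -1e-12 <= beta <= 1 + 1e-12:
            beta = float(np.clip(beta, 0.0, 1.0))
            hits.append((pts[i] + beta * e, float(s[i] + beta * (s[i + 1] - s[i]))))
    return hits


def reference_landmarks(outline: HookOutline,
                        distal_window=(0.4, 1.0), proximal_window=(0.0, 0.4),
                        step: float = 0.02) -> DerivedLandmarks:
    """Derived landmarks by exhaustive search (see module docstring)."""
    outline = outline.to_um()
    T = outline.tip
    B = outline.articulation_base
    if np.linalg.norm(T - B) < 1e-12:
        raise GeometryError("tip coincides with articulation base")

    outer, outer_s = _resample(outline.outer_edge, step)
    inner, inner_s = _resample(outline.inner_edge, step)

    Z_out, z_s, z_d = _zenith(outer, outer_s, B, T, *distal_window)
    if z_d < 1e-6:
        raise GeometryError("outer zenith degenerate (straight hook)")
    u = (T - B) / np.linalg.norm(T - B)
    F_AD = B + u * float((Z_out - B) @ u)

    hits = _line_hits(F_AD, Z_out - F_AD, inner, inner_s)
    pl_len = float(np.linalg.norm(Z_out - F_AD))
    pl_dir = (Z_out - F_AD) / pl_len
    hits = [h for h in hits
            if -1e-9 <= float((h[0] - F_AD) @ pl_dir) <= pl_len + 1e-9]
    if not hits:
        raise GeometryError("PL segment misses the inner edge")
    P_in, p_s = max(hits, key=lambda h: float((h[0] - F_AD) @ pl_dir))

    H_heel, _, _ = _zenith(outer, outer_s, B, T, *proximal_window)

    # blade sections: tip to the PL intercept on each edge
    ib_mask = inner_s <= p_s + 1e-9
    iblade = np.vstack([inner[ib_mask], P_in])
    iblade_s = np.concatenate([inner_s[ib_mask], [p_s]])
    Zi, _, _ = _zenith(iblade, iblade_s, T, Z_out, 0.0, 1.0)
    blade = outer[outer_s <= z_s + 1e-9]
    blade_s = outer_s[outer_s <= z_s + 1e-9]
    Zo, _, _ = _zenith(blade, blade_s, T, Z_out, 0.0, 1.0)

    lo, hi = outline.effective_straight_range()
    straight = outline.inner_edge[lo:hi]
    centroid = straight.mean(axis=0)
    _, _, vt = np.linalg.svd(straight - centroid, full_matrices=False)
    axis_dir = vt[0]
    if axis_dir @ (straight[0] - straight[-1]) < 0:
        axis_dir = -axis_dir

    return DerivedLandmarks(
        tip=T, base=B, Z_out=Z_out, F_AD=F_AD, P_in=P_in, H_heel=H_heel,
        Z_inner_blade=Zi, Z_outer_blade=Zo,
        shaft_axis_point=centroid, shaft_axis_direction=axis_dir,
        Z_out_arclength=z_s, P_in_arclength=p_s,
    )


def reference_measurements(outline: HookOutline,
                           distal_window=(0.4, 1.0), proximal_window=(0.0, 0.4),
                           step: float = 0.02) -> MeasurementSet:
    """All measurements by the brute-force route, as a :class:`MeasurementSet`."""
    outline = outline.to_um()
    lm = reference_landmarks(outline, distal_window, proximal_window, step)
    T, B, Z, F, P, H = lm.tip, lm.base, lm.Z_out, lm.F_AD, lm.P_in, lm.H_heel

    def dist(p, q):
        return float(np.sqrt(((p - q) ** 2).sum()))

    def perp(p, a, b):
        u = (b - a) / dist(a, b)
        return float(abs((p[0] - a[0]) * u[1] - (p[1] - a[1]) * u[0]))

    def ang(v1, v2):
        c = float(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)))
        return float(np.degrees(np.arccos(max(-1.0, min(1.0, c)))))

    values = {
        "AD": dist(T, B),
        "PSW": dist(B, H),
        "PL": dist(F, Z),
        "DSW": dist(P, Z),
        "ICL": perp(lm.Z_inner_blade, T, Z),
        "OCL": perp(lm.Z_outer_blade, T, Z),
        "DPL": dist(T, Z),
        "ISL": dist(P, B),
        "OSL": dist(Z, H),
        "PCA": ang(F - Z, T - Z),
        "OAA": ang(H - Z, T - Z),
        "IAA": ang(B - P, T - P),
    }
    proj = np.concatenate([outline.inner_edge, outline.outer_edge]) @ lm.shaft_axis_direction
    values["HL"] = float(proj.max() - proj.min())
    if outline.handle is not None:
        values["HNL"] = dist(*outline.handle)
    return MeasurementSet(values=values, specimen_id=outline.specimen_id)
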
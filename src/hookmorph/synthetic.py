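"""Synthetic data: published summary distributions and parametric hook shapes.

Two generators make every downstream stage testable without micrographs:

* :func:`generate_measurements` draws per-specimen measurement tables from
  the published per-species summary statistics (mean, SD, observed range of
  the 14 hook/handle variables for *Paradiplozoon vaalense*, *Diplozoon
  paradoxum* and *Paradiplozoon ichthyoxanthon*), exposed by
  :func:`species_presets`.  Variables are drawn independently — the source
  tables print only marginal summaries, so no covariance structure can be
  emulated (see docs/methods.md).

* :func:`build_hook_outline` constructs a parametric hook outline (straight
  tapering shaft, circular-annulus blade, tapered point, Gaussian heel
  bulge) together with ground-truth landmarks and measurements computed by
  the brute-force reference engine on a densely sampled copy.  These are the
  oracle fixtures for the geometry engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .errors import ConstructionError
from .geometry import DerivedLandmarks, HookOutline, MeasurementSet
from .reference import reference_landmarks, reference_measurements
from .variables import ANGLE_VARIABLES, VARIABLE_NAMES

__all__ = [
    "VariableParams",
    "SpeciesParams",
    "HookShapeParams",
    "species_presets",
    "generate_measurements",
    "build_hook_outline",
]


@dataclass(frozen=True)
class VariableParams:
    """Summary distribution of one measurement: mean, SD and observed range.

    Units are micrometres for lengths and degrees for the three angles.
    """

    name: str
    mean: float
    sd: float
    range_low: float
    range_high: float

    def __post_init__(self) -> None:
        if self.name not in VARIABLE_NAMES:
            raise ValueError(f"unknown variable name {self.name!r}")
        if self.sd < 0:
            raise ValueError(f"{self.name}: sd must be >= 0")
        if not (self.range_low <= self.mean <= self.range_high):
            raise ValueError(f"{self.name}: mean outside [range_low, range_high]")

    @property
    def units(self) -> str:
        return "deg" if self.name in ANGLE_VARIABLES else "um"


@dataclass(frozen=True)
class SpeciesParams:
    """Per-species summary distributions for all 14 variables."""

    species: str
    n_default: int
    variables: dict[str, VariableParams]

    def __post_init__(self) -> None:
        if set(self.variables) != set(VARIABLE_NAMES):
            missing = set(VARIABLE_NAMES) - set(self.variables)
            extra = set(self.variables) - set(VARIABLE_NAMES)
            raise ValueError(f"species {self.species!r}: missing={sorted(missing)} "
                             f"extra={sorted(extra)}")
        if self.n_default < 0:
            raise ValueError("n_default must be >= 0")


# (mean, sd, range_low, range_high) per variable; lengths um, angles degrees.
_PRESET_TABLE: dict[str, tuple[int, dict[str, tuple[float, float, float, float]]]] = {
    "P. vaalense": (8, {
        "HL":  (18.53, 0.39, 17.77, 19.35),
        "HNL": (41.45, 0.96, 39.23, 42.07),
        "AD":  (12.80, 0.33, 12.55, 13.41),
        "PSW": (3.72, 0.26, 3.26, 4.16),
        "PL":  (7.95, 0.30, 7.36, 8.44),
        "DSW": (2.81, 0.22, 2.61, 3.18),
        "ICL": (1.89, 0.18, 1.67, 2.10),
        "OCL": (3.06, 0.27, 2.80, 3.52),
        "PCA": (13.43, 2.81, 9.44, 17.81),
        "ISL": (12.08, 0.36, 11.31, 12.83),
        "IAA": (85.13, 5.45, 76.57, 92.98),
        "OSL": (15.94, 0.41, 15.05, 16.75),
        "OAA": (78.70, 3.44, 73.72, 84.57),
        "DPL": (7.46, 0.45, 6.70, 8.06),
    }),
    "D. paradoxum": (4, {
        "HL":  (30.67, 0.65, 30.02, 31.37),
        "HNL": (67.70, 2.34, 63.95, 70.38),
        "AD":  (22.87, 0.69, 22.02, 23.71),
        "PSW": (3.66, 0.15, 3.42, 3.80),
        "PL":  (13.08, 0.31, 12.62, 13.49),
        "DSW": (3.38, 0.21, 3.16, 3.69),
        "ICL": (3.37, 0.20, 3.05, 3.60),
        "OCL": (4.85, 0.28, 4.42, 5.22),
        "PCA": (9.49, 2.28, 7.50, 13.15),
        "ISL": (22.81, 0.58, 22.22, 23.76),
        "IAA": (77.76, 3.44, 74.30, 83.17),
        "OSL": (25.34, 0.51, 24.75, 26.08),
        "OAA": (75.35, 3.00, 72.55, 80.39),
        "DPL": (12.77, 0.29, 12.39, 13.12),
    }),
    "P. ichthyoxanthon": (5, {
        "HL":  (25.23, 0.57, 24.78, 26.29),
        "HNL": (55.25, 3.23, 51.91, 59.30),
        "AD":  (18.08, 0.67, 17.65, 19.40),
        "PSW": (4.10, 0.28, 3.66, 4.53),
        "PL":  (10.54, 0.11, 10.39, 10.71),
        "DSW": (3.85, 0.18, 3.59, 4.12),
        "ICL": (2.53, 0.16, 2.42, 2.85),
        "OCL": (4.34, 0.20, 4.00, 4.59),
        "PCA": (15.46, 3.95, 10.68, 21.54),
        "ISL": (16.59, 0.54, 15.63, 17.22),
        "IAA": (89.69, 4.72, 84.71, 96.61),
        "OSL": (21.03, 0.34, 20.55, 21.48),
        "OAA": (79.91, 3.29, 76.49, 85.84),
        "DPL": (10.03, 0.18, 9.86, 10.37),
    }),
}


def species_presets() -> dict[str, SpeciesParams]:
    """Published per-species summary statistics for the three diplozoid species.

    ``n_default`` holds the group sizes used in the discriminant analysis
    (8 / 4 / 5); the hook summaries for *P. vaalense* were originally
    reported over 10 specimens, of which 8 entered the multivariate
    analysis.
    """
    out: dict[str, SpeciesParams] = {}
    for species, (n_default, table) in _PRESET_TABLE.items():
        variables = {
            name: VariableParams(name, *vals) for name, vals in table.items()
        }
        out[species] = SpeciesParams(species=species, n_default=n_default,
                                     variables=variables)
    return out


def _species_prefix(species: str) -> str:
    parts = species.replace(".", "").split()
    return "".join(p[0] for p in parts[:-1]).upper() + parts[-1][:2].capitalize()


def generate_measurements(params: dict[str, SpeciesParams] | None = None,
                          n_per_species: dict[str, int] | int | None = None,
                          seed: int = 0,
                          truncate: bool = False) -> pd.DataFrame:
    """Draw a measurement table from per-species Gaussian distributions.

    Each variable is drawn independently as Normal(mean, sd); with
    ``truncate=True`` values are redrawn until they fall inside the
    observed range.  Deterministic given ``seed``.

    Returns a DataFrame with columns ``specimen_id``, ``species`` and the
    14 variables in canonical order.
    """
    if params is None:
        params = species_presets()
    if n_per_species is None:
        counts = {sp: p.n_default for sp, p in params.items()}
    elif isinstance(n_per_species, int):
        counts = {sp: n_per_species for sp in params}
    else:
        unknown = set(n_per_species) - set(params)
        if unknown:
            raise ValueError(f"unknown species in n_per_species: {sorted(unknown)}")
        counts = {sp: int(n_per_species.get(sp, params[sp].n_default)) for sp in params}
    if any(n < 0 for n in counts.values()):
        raise ValueError("specimen counts must be >= 0")

    rng = np.random.default_rng(seed)
    frames = []
    for species, sp in params.items():
        n = counts[species]
        data: dict[str, np.ndarray] = {}
        for name in VARIABLE_NAMES:
            vp = sp.variables[name]
            vals = rng.normal(vp.mean, vp.sd, size=n)
            if truncate and vp.sd > 0:
                for _ in range(10_000):
                    bad = (vals < vp.range_low) | (vals > vp.range_high)
                    if not bad.any():
                        break
                    vals[bad] = rng.normal(vp.mean, vp.sd, size=int(bad.sum()))
                else:
                    raise RuntimeError(f"truncation failed to converge for {name}")
            data[name] = vals
        prefix = _species_prefix(species)
        frame = pd.DataFrame(data)
        frame.insert(0, "species", species)
        frame.insert(0, "specimen_id", [f"{prefix}{i + 1:03d}" for i in range(n)])
        frames.append(frame)
    if not frames:
        return pd.DataFrame(columns=["specimen_id", "species", *VARIABLE_NAMES])
    out = pd.concat(frames, ignore_index=True)
    return out[["specimen_id", "species", *VARIABLE_NAMES]]


# ---------------------------------------------------------------------------
# parametric hook shapes


@dataclass(frozen=True)
class HookShapeParams:
    """Shape grammar for a parametric diplozoid-style hook.

    The hook is a straight strip (shaft) whose width tapers linearly from
    ``shaft_width_proximal`` at the articulation base to
    ``shaft_width_distal`` at the blade junction, a circular-annulus blade
    of inner radius ``blade_inner_radius`` sweeping ``blade_arc_degrees``,
    and a point: over the last ``point_taper_fraction`` of the sweep both
    edges taper linearly to a single tip vertex on the annulus midline.
    A Gaussian bulge of height ``heel_bulge_height`` centred at
    ``heel_bulge_position`` (fraction of shaft length from the base) models
    the heel on the outer shaft edge.  ``resolution`` is the vertex count
    per edge section (arc and shaft each); zenith landmarks can only fall
    on digitized vertices, so sub-vertex localisation improves with it.
    ``rigid_pose`` is (rotation degrees, dx, dy).  All lengths in
    micrometres.
    """

    shaft_length: float = 16.0
    shaft_width_proximal: float = 2.4
    shaft_width_distal: float = 1.6
    blade_inner_radius: float = 2.5
    blade_arc_degrees: float = 190.0
    point_taper_fraction: float = 0.35
    handle_length: float = 41.0
    heel_bulge_height: float = 3.0
    heel_bulge_position: float = 0.12
    resolution: int = 300
    rigid_pose: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        positives = {
            "shaft_length": self.shaft_length,
            "shaft_width_proximal": self.shaft_width_proximal,
            "shaft_width_distal": self.shaft_width_distal,
            "blade_inner_radius": self.blade_inner_radius,
            "handle_length": self.handle_length,
        }
        for name, v in positives.items():
            if v <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.blade_arc_degrees < 270:
            raise ValueError("blade_arc_degrees must be in (0, 270)")
        if not 0 < self.point_taper_fraction <= 1:
            raise ValueError("point_taper_fraction must be in (0, 1]")
        if self.resolution < 50:
            raise ValueError("resolution must be >= 50")
        if self.heel_bulge_height < 0 or not 0 <= self.heel_bulge_position <= 0.5:
            raise ValueError("heel bulge parameters out of range")


def _hook_edges(p: HookShapeParams, resolution: int):
    """Inner/outer edges (tip->base) of the hook in the local frame."""
    L, wp, wd = p.shaft_length, p.shaft_width_proximal, p.shaft_width_distal
    r, theta = p.blade_inner_radius, np.deg2rad(p.blade_arc_degrees)
    f = p.point_taper_fraction
    C = np.array([L, wd / 2 + r])  # blade centre of curvature

    phi = np.linspace(theta, 0.0, resolution)  # tip -> blade/shaft junction
    taper = np.clip((phi - theta * (1 - f)) / (theta * f), 0.0, 1.0)
    r_in = r + (wd / 2) * taper
    r_out = r + wd - (wd / 2) * taper
    ray = np.column_stack([np.sin(phi), -np.cos(phi)])
    inner_arc = C + r_in[:, None] * ray
    outer_arc = C + r_out[:, None] * ray

    x = np.linspace(L, 0.0, resolution)[1:]  # junction vertex already on the arc
    half_w = (wp + (wd - wp) * x / L) / 2
    inner_shaft = np.column_stack([x, half_w])
    sigma = 0.08 * L  # heel knob width
    bulge = p.heel_bulge_height * np.exp(-(((x - p.heel_bulge_position * L) / sigma) ** 2))
    outer_shaft = np.column_stack([x, -half_w - bulge])

    inner = np.vstack([inner_arc, inner_shaft])
    outer = np.vstack([outer_arc, outer_shaft])
    straight_range = (len(inner_arc) - 1, len(inner))
    return inner, outer, straight_range


def _apply_pose(pts: np.ndarray, pose: tuple[float, float, float]) -> np.ndarray:
    th = np.deg2rad(pose[0])
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    return np.atleast_2d(pts) @ R.T + np.array(pose[1:])


def build_hook_outline(p: HookShapeParams, specimen_id: str = "synthetic",
                       ground_truth: bool = True,
                       ) -> tuple[HookOutline, DerivedLandmarks | None, MeasurementSet | None]:
    """Construct a parametric hook outline with brute-force ground truth.

    Returns ``(outline, landmarks, measurements)``.  The ground truth is
    computed by :mod:`hookmorph.reference` on an independently constructed
    copy sampled at >= 20x the requested resolution (and step <= 0.02 um),
    so it is the oracle against which the production geometry engine is
    validated.  Pass ``ground_truth=False`` to skip that (faster).

    Raises :class:`ConstructionError` if the parameters self-intersect.
    """
    inner, outer, straight_range = _hook_edges(p, p.resolution)
    ring = np.vstack([inner, outer[::-1][:-1]])
    if not Polygon(ring).is_valid:
        raise ConstructionError("shape parameters produce a self-intersecting outline")

    pose = p.rigid_pose
    handle_local = (np.array([0.0, 0.0]), np.array([-p.handle_length, 0.0]))
    outline = HookOutline(
        specimen_id=specimen_id,
        inner_edge=_apply_pose(inner, pose),
        outer_edge=_apply_pose(outer, pose),
        articulation_base=_apply_pose(np.array([0.0, 0.0]), pose)[0],
        straight_range=straight_range,
        handle=(_apply_pose(handle_local[0], pose)[0], _apply_pose(handle_local[1], pose)[0]),
    )
    if not ground_truth:
        return outline, None, None

    # densely sampled copy: >= 20x resolution and arc-length step <= 0.02 um
    perimeter = p.shaft_length * 2 + np.deg2rad(p.blade_arc_degrees) * (
        p.blade_inner_radius + p.shaft_width_distal) * 2
    dense_res = max(20 * p.resolution, int(np.ceil(perimeter / 0.02)))
    d_inner, d_outer, d_range = _hook_edges(p, dense_res)
    dense = HookOutline(
        specimen_id=specimen_id,
        inner_edge=_apply_pose(d_inner, pose),
        outer_edge=_apply_pose(d_outer, pose),
        articulation_base=outline.articulation_base,
        straight_range=d_range,
        handle=outline.handle,
    )
    gt_landmarks = reference_landmarks(dense)
    gt_measurements = reference_measurements(dense)
    return outline, gt_landmarks, gt_measurements
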
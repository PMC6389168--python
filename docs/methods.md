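# Methods

`hookmorph` implements a landmark/vector measurement scheme for the central
hooks of diplozoid monogeneans (Platyhelminthes: Diplozoidae) and the
multivariate statistics used to delimit species on those measurements. This
note records the model, its assumptions, the tunable parameters, and the
design decisions taken where the underlying scheme is ambiguous.

## The measurement scheme

A hook is digitized as two ordered polylines in a 2-D Cartesian frame — the
inner (concave) and outer (convex) edge, both running from the point tip
`T` to the articulation end — plus the landmark `B`, the centre of the base
of the hook–handle articulation, and optionally the two handle landmarks.
Coordinates are micrometres after applying a per-record scale factor. The
scheme assumes the sclerite was imaged flat; no image-axis flipping is
performed (a caller digitizing from images with a downward y-axis must flip
first).

All derived landmarks reduce to three primitive constructions:

* **Zenith** — the point of an edge at maximal perpendicular distance from
  a reference line, searched inside a window of projection parameters along
  that line. The edge is resampled at a fixed arc-length step (default
  0.02 µm), the exact window-boundary crossing points are inserted, and
  ties are broken by the smallest arc length from the tip.
* **Perpendicular foot** — orthogonal projection of a point onto a line.
* **Line/edge intercept** — intersection of a line segment with a polyline.

From `T`, `B`, the outer-edge zenith `Z_out` relative to the `B→T` line
(the AD vector), its foot `F_AD`, the PL line through `F_AD` and `Z_out`,
the PL/inner-edge intercept `P_in`, and the heel zenith `H_heel`, the 14
variables follow: AD = |T−B|, PSW = |B−H_heel|, PL = |F_AD−Z_out|,
DSW = |P_in−Z_out|, ISL = |P_in−B|, OSL = |Z_out−H_heel|, DPL = |T−Z_out|,
ICL/OCL = perpendicular distances of the inner-/outer-blade zeniths to the
chord `T–Z_out`, PCA/OAA at vertex `Z_out`, IAA at vertex `P_in`, HL = the
projection extent of the whole outline on the shaft axis, and HNL = the
handle tip–base distance. The shaft axis is a total-least-squares line
through the flagged straight section of the inner edge (default: the
proximal 40 % when unflagged — the "straight part" is otherwise a visual
judgement).

### Decisions where the scheme is ambiguous

* **Zenith windows.** The distal (outer-zenith) and proximal (heel) searches
  are split at 0.4 of the `B→T` projection span; both windows are
  configurable. The split is a convention: the two zeniths are otherwise
  distinguished only pictorially.
* **PL intercept.** The PL line can cross the inner edge more than once —
  in strongly recurved hooks the point section crosses it too. `P_in` is
  the crossing of the `F_AD→Z_out` *segment* adjacent to `Z_out`, so DSW is
  always the width of the sclerite at that section; any rule keyed to the
  nearest crossing from `F_AD` degenerates to the point tip for blade arcs
  beyond roughly 195°.
* **Blade restriction.** The blade zeniths for ICL/OCL are searched on each
  edge from the tip to the PL intercept on that edge (`P_in` inner, `Z_out`
  outer); without the restriction the inner-edge search escapes onto the
  shaft, whose perpendicular distance to the chord dwarfs the blade's.
* **PCA convention.** PCA is the interior angle at vertex `Z_out` between
  the rays to `F_AD` and to `T` (the acute reading, ~6–15° on realistic
  hooks). Taking the angle between the raw direction vectors instead gives
  the supplement (~170°).
* **DPL.** Defined as the point-to-point distance |T−Z_out|; a
  "perpendicular distance" between two named points is ill-formed. Note
  this implies DPL ≥ PL identically, a constraint the published summary
  means do not satisfy for one species — one reason the printed tables
  cannot be regenerated from their own marginals.
* **Angles** are interior angles in (0°, 180°], reported in degrees.
* **Degenerate inputs** raise typed errors: coincident tip/base, no blade
  curvature (outer zenith indistinct from the AD line), a PL segment that
  misses the inner edge, coincident angle vertices. Coincident handle
  landmarks return HNL = 0 with a warning.

### Numerical behaviour

Zenith landmarks can only fall on sampled points, so their localisation
error is about half the effective sampling step — the larger of the
densification step (0.02 µm default; anything ≤ 0.1 µm is adequate) and the
outline's own vertex spacing. Distance-type outputs are second-order
accurate at smooth zeniths; position-type outputs (OSL, DPL, the chord for
ICL/OCL) inherit the first-order localisation error. On the parametric
fixtures (vertex spacing ≤ 0.05 µm) every variable agrees with a 20×-dense
brute-force reference within 0.3 % / 0.15°, comfortably inside the 0.5 % /
0.5° band asserted by the tests; doubling either resolution changes outputs
by well under 0.2 %.

## Synthetic data

Two generators make the pipeline testable without micrographs.

**Measurement tables.** Per-species values are drawn as independent
Gaussians from the published summary statistics (mean, SD, observed range)
of the three species studied — *Paradiplozoon vaalense*, *Diplozoon
paradoxum*, *Paradiplozoon ichthyoxanthon* — with discriminant-analysis
group sizes 8/4/5 as the default. Truncation to the observed ranges is off
by default (ranges are sample extremes, not distribution bounds).
Independence is forced, not chosen: only marginal summaries are published.
Real hook measurements are strongly correlated within a specimen (they are
all sizes of one structure), so the synthetic tables understate joint
separability for correlated variable sets and overstate the independence of
evidence across variables. Consequences: (a) perfect classification on
these tables shows the pipeline recovers the published separation *given
the printed effect sizes*, not that the original raw data are reproduced;
(b) pairwise rank tests on weakly separated variables (DSW, OCL: ~2.1–2.4
pooled SD for the *D. paradoxum*–*P. ichthyoxanthon* pair) reach
significance in only ~half the draws, whereas all variables with ≥ ~4.4 SD
minimum pairwise separation do so in ≥ 95 % of draws.

**Parametric hooks.** A shape grammar produces hook-like outlines with
known ground truth: a straight shaft (width tapering linearly from the
base), a circular-annulus blade, a point that tapers both edges to a single
tip vertex over the last fraction of the sweep, and a Gaussian heel knob on
the proximal outer edge. The knob is anatomically motivated (the heel is a
proximal outer bulge near the articulation) and numerically necessary: on a
knob-less strip the proximal zenith pins to the search-window boundary
rather than a smooth interior maximum. The validated fixture family
(shaft 14–18 µm, blade radius 2.2–3.2 µm, arc 175–205°, knob height
2.6–3.4 µm) yields long-shaft recurved hooks on the published measurement
scale (AD ≈ 17 µm, PL ≈ 7 µm, PCA ≈ 6°). Ground truth is computed by an
independent brute-force engine (exhaustive vertex argmax, per-segment
intersection solves, SVD axis) on a ≥ 20×-dense copy; the production engine
shares no code with it. The grammar does not emulate digitization noise,
edge roughness, partial occlusion or out-of-plane tilt — agreement on
fixtures validates the geometry, not robustness to poor digitization.

## Statistics

All multivariate analyses use listwise-complete rows; per-variable
summaries use available cases (this mechanically reproduces differing n
between summary and classification tables). Conventions follow the common
commercial stepwise-LDA implementation:

* **Equality of group means:** per variable, Wilks' Λ = SSW/SST and
  F = ((1−Λ)/Λ)·((N−k)/(k−1)) with df (k−1, N−k); the identity is exact by
  construction and cross-checked against one-way ANOVA.
* **Stepwise selection** (F-to-enter 3.84, F-to-remove 2.71, both
  configurable): at each step the candidate minimizing the overall
  Λ = |W|/|T| enters if its partial-Λ F with df (k−1, N−k−p) passes;
  entered variables drop when their F-to-remove falls below the exit
  threshold; candidates with pooled within-group tolerance (1−R²) below
  10⁻³ are skipped with a logged warning. At N = 17 with 14 pure-noise
  candidates the modal outcome is the empty selection.
* **Canonical functions:** generalized eigenproblem B·v = λ·W·v, functions
  scaled to unit pooled within-group score variance, sign fixed by making
  the largest-magnitude coefficient positive, scores centred on the grand
  mean. The structure matrix holds pooled within-group correlations of
  *every* candidate variable with each function.
* **Classification:** smallest Mahalanobis distance under the pooled
  within-group covariance with equal priors (configurable). Cross-validation
  is leave-one-out with coefficients refit per fold but the selected
  variable set frozen, matching the convention of the reported
  cross-validated tables. Assignments are invariant under affine rescaling
  of any variable.
* **Kruskal-Wallis post hoc:** the global test uses the tie-corrected H
  (defined as 0 when all observations are equal) with a χ²(k−1) p; an
  exact full-enumeration p is available for small N (≤ ~8). The pairwise
  default is exact Mann-Whitney with Bonferroni correction over the
  k(k−1)/2 pairs. Dunn's joint-rank z test is provided but not default: at
  group sizes 8/4/5 its z for the middle-ranked pair is bounded at ~1.33
  regardless of separation, so it can never flag that pair — a small-sample
  property worth knowing before trusting any "post hoc" label.

## Problem sizes

The test suite and drivers use 100 generator seeds for the classification
reproduction, 100 randomized fixtures for the geometry/oracle comparison
(40 in the analysis driver), n = 200/species for parameter recovery, full
permutation enumeration at N ≤ 8 for the exact Kruskal-Wallis checks, and
n = 10⁵ draws for generator-convergence checks. These sizes give
comfortable statistical margins for every asserted property while keeping
a full run in the low minutes.

## Known limitations

* No automatic landmark detection or outline extraction from raster SEM
  images; the package starts at labeled coordinates. Clamp sclerites are
  out of scope (no measurement protocol exists for isolated clamps).
* The independence of simulated variables is a documented misfit to real
  morphometric data (above).
* The published per-table statistics (exact Λ/F/p values, specimen means)
  derive from raw measurements that were never deposited and cannot be
  regenerated from marginal summaries; the package reproduces the
  *procedures* and the headline separation result, not those table entries.
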
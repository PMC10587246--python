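# Methods

`retquant` quantifies diabetic-retinopathy (DR) lesions on the ETDRS
seven-standard-field (7SF) grid and grades severity with explicit rule
engines. This note records the model, the defaults that matter, the
numerical choices, and what the synthetic cohorts do and do not
demonstrate.

## Coordinate system and the spherical eye model

Annotations live in an eye-centered angular chart: the fovea at the
origin, longitude along the disc–fovea axis (temporal positive for right
eyes; left-eye layouts are the mirror image), latitude superior-positive,
both in degrees of visual angle. The chart is azimuthal-equidistant
about the fovea: a point at chart distance ε degrees from the origin lies
at central angle ε on a model sphere. One chart degree therefore spans a
fixed retinal arc `mm_per_degree`.

`mm_per_degree` (default **0.291 mm/deg**, the emmetropic schematic-eye
retinal scale) is the single master scale constant; the model sphere
radius follows from it, `R = mm_per_degree·180/π ≈ 16.67 mm`. Treating
the scale as primary keeps reported mm² areas consistent with the
conversion clinicians use, and makes every area exactly quadratic in the
scale (doubling `mm_per_degree` quadruples areas). Both constants are
configurable.

Lesion and field polygons have straight edges in the chart. Their
surface area on the sphere is obtained by integrating the chart's area
correction factor `sin ε / ε` with a Green's-theorem line integral
(32-point Gauss–Legendre per edge), which is exact to quadrature
precision: a chart circle of radius ε reproduces the spherical-cap
closed form `2πR²(1−cos ε)` to the accuracy of the circle's polygonal
approximation (~6·10⁻⁶ at 256 segments). The stereographic projection
used for planar processing maps from the anterior pole to the plane
tangent at the fovea (`ρ = 2R tan(ε/2)`); it is conformal, invertible to
machine precision, and carries the usual `sec⁴(ε/2)` area magnification,
which the area-corrected pipeline removes.

## The seven-field layout

Seven equal circles of default radius **15°** (30°-diameter standard
fields): field 1 on the disc, field 2 on the fovea, field 3 temporal to
the fovea with its nasal edge at the fovea, fields 4/5
superior/inferior-temporal and 6/7 superior/inferior-nasal, tangent to
the meridians through the disc center. The placement is a configurable
table of per-field offsets (in units of the field radius, along the
temporal and superior axes, anchored at disc or fovea), so other
arrangements can be encoded without code changes.

Within the circles' union, every point is assigned to exactly one field:
the nearest field center, ties to the lowest field index. This is a
declared convention — published field protocols do not define ownership
of the circles' overlap zones — and it makes the per-field areas an
exact partition of any lesion's in-grid area. The partition is
implemented by clipping nearest-center dominance (Voronoi) cells to the
union; Monte-Carlo point-assignment oracles in the test suite confirm
the fractions to within 0.01.

## Fractional frequency and area

A lesion's count contribution is split across fields in proportion to
its spherical area in each field's region, so per-field frequencies are
non-integer while (per type) the seven field totals plus the outside
mass recover the raw lesion count exactly (conservation is asserted to
1e−6 across the synthetic cohorts). Area-proportional splitting is the
only convention consistent with non-integer totals that still sum to the
raw count. Lesions wholly outside the union contribute zero to grid
metrics. Fibrous proliferation (PFD/PFE) is quantified internally but
suppressed from summary reports, as it does not drive severity; venous
beading/loop areas are computed like any polygon, with suppression of
their area columns left to report options.

Self-intersecting lesion polygons are dropped with a warning by default
(one bad polygon should not void an eye); a strict mode raises with eye
and lesion identifiers. Zero-extent degenerates count as zero area.

## Severity rule engines

Human grading against reference standard photographs cannot be
formalized exactly; the engines encode a simplified, fully documented
rule table whose thresholds are configuration constants:

- **ICDR** (0–4): proliferative lesions (NVE, NVD, preretinal/vitreous
  hemorrhage) → 4; else the 4-2-1 rule → 3 (more than 20 hemorrhages in
  each of four fovea-centered quadrants, venous beading in ≥ 2
  quadrants, or prominent IRMA — in-grid IRMA area ≥ 0.10 mm² — in ≥ 1
  quadrant); microaneurysms only → 1; questionable-DR eyes → 1; any
  other lesion → 2; clean eye → 0. Quadrants are fovea-centered
  half-plane sectors aligned to the disc–fovea axis, clipped to the
  grid; hemorrhage tallies accumulate each lesion's in-grid fraction at
  its centroid quadrant and round half-up to whole lesions.
- **Protocol AA** (10–90): reported within the band the ICDR category
  implies. 10/12 split by a non-DR-abnormality flag; 14 vs 20 by the
  questionable flag; NPDR tiers 35/43/47 by the number of involved
  fields 2–7 (a field is involved when any active NPDR lesion class
  reaches fractional frequency 0.5 there; tiers step at 2 and 4 fields);
  53 vs 53E by whether one or ≥ 2 of the 4-2-1 criteria are met; PDR
  tiers: high-risk "71/75" when NVD is present or NVE coexists with
  preretinal/vitreous hemorrhage, 65 for hemorrhage or extensive NVE
  (≥ 0.5 mm²), 61 for lesser NVE, 60 for inactive proliferation.
  High-risk and cannot-grade sublevels are reported as collapsed tiers.

Both engines are deterministic, record a fired-rule trace, and satisfy a
scale-consistency invariant (every ICDR/AA pair lies in the band
mapping). These tier thresholds are this package's conventions, not any
study's exact internal criteria.

## Synthetic cohorts

The generator emulates per-severity lesion statistics of a large
multicenter clinical UWF cohort:

- **Counts** per (ICDR level, class): negative binomial parameterized by
  the configured mean/SD — the defaults are overdispersed in almost all
  cells. Cells at or below Poisson dispersion (a few printed defaults
  are, e.g. venous loop at moderate NPDR) fall back to Poisson; a strict
  NB mode raises instead.
- **Per-lesion areas**: log-normal with mean/SD derived as per-eye total
  area over mean count. Lesions are 16-gon ellipses realizing the drawn
  spherical area exactly (random aspect 0.55–1 and orientation).
- **Placement**: isotropic density ∝ exp(−c·ε) with
  `spatial_concentration` c = **0.08 /deg** by default (mean eccentricity
  25°, central-weighted, consistent with lesions being more numerous
  centrally; the value is a free parameter of this package). In-grid
  lesions are placed wholly inside the 7SF union so sampled counts are
  exactly the in-grid counts; rare large proliferative membranes (> 8°
  nominal radius) only anchor their center in the grid and may straddle
  its edge, preserving the heavy log-normal area tails untruncated.
  `peripheral_fraction` (default 0.25) adds extra out-of-grid lesions
  per in-grid lesion, which exist in the eye but never enter grid
  metrics.
- **Level 0** eyes are lesion-free; **level 1** eyes carry
  microaneurysms only.
- **Constraint repair** (default on) edits a sampled eye minimally until
  the ICDR engine returns the designed level: severe eyes get
  redistributed hemorrhages when ≥ 84 are present, relocated venous
  beading when ≥ 2 are present, an enlarged IRMA when one exists, or one
  added prominent IRMA otherwise; moderate eyes are demoted out of
  accidental 4-2-1 configurations by relocation; PDR eyes receive one
  NVE if no proliferative lesion was drawn. Repair necessarily distorts
  the sampled distributions of grade-defining classes, so the
  calibration property (sample means within 3 SE of the configured
  values, 500 eyes/level) is asserted on the pure sampling stage
  (`repair=False`), while grade recovery (100%) is asserted on repaired
  output. Both switches are part of `CohortConfig`.
- The **simulated second grader** perturbs the ICDR label (±1 level with
  probability `grader_error_rate`, default 0.05), not the segmentation,
  because inter-grader agreement is computed on severity scores. The
  designed Protocol AA truth level is drawn uniformly from the band of
  the designed ICDR level.

What passing tests show: the geometry, accounting, grading logic and
statistics behave correctly on data with realistic marginal count/area
distributions and central-weighted placement. What they do not show:
performance on real images — synthetic eyes have no segmentation noise,
no correlated lesion clustering, no image-quality gradients, and
ellipse-shaped lesions only.

## Statistics

Kruskal–Wallis H on mid-ranks with the standard tie-correction divisor
and chi-square p (df = groups − 1; identical pooled values give H = 0,
p = 1). Dunn's pairwise z from mean-rank differences with tie-corrected
variance, Bonferroni-adjusted by k(k−1)/2 within each lesion-metric
family (no cross-metric correction). Unweighted Cohen's kappa with
explicit observed/expected agreement; degenerate marginals raise.
Severity shares are rounded half-up to one decimal (so 6.25% prints as
6.3). Exact-permutation enumerations, scipy and hand-computed tables
serve as independent oracles in the tests; the implementation itself is
the rank-formula code above.

## Problem sizes and determinism

Default verification sizes: calibration 500 eyes/level, conservation
1000 eyes, grading recovery and kappa 1000 eyes, null-size simulation
2000 replicates of 4×30, Monte-Carlo oracles 10⁵–10⁶ points. All
randomness flows through a single seeded `numpy` generator per run;
identical configuration and seed reproduce byte-identical cohorts and
output files.

## Known limitations

- Field-placement tangency constants and the overlap-partition rule are
  conventions; vendor grid masks may differ in the overlap zones.
- The AA tier thresholds (field counts, prominence areas) are package
  defaults, not validated clinical cut-points.
- Per-lesion area SDs derived as total-SD/mean-count inflate per-lesion
  dispersion when counts vary strongly; the resulting log-normals are
  heavy-tailed, which is conservative for calibration tests.
- The simulated grader's symmetric ±1 error model is a simplification;
  real grader disagreement is asymmetric across severity boundaries.
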
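# Methods

## The force balance and its conventions

The package's central model treats a hovering, autorotating samara as a
rotating blunt body whose weight is carried by a single lumped
aerodynamic force acting on the projected plan-view area:

    m g = ½ C_D ρ V_d² A |cos θ|.

Form drag and lift both oppose descent; lumping them loses their
decomposition but gains a single interspecific drag coefficient that can
be compared across species and against altered specimens.

Conventions and defaults:

* **Air density** ρ = 1.23 kg/m³ (dry air near 15 °C at sea level) and
  g = 9.81 m/s². Both are plain fields of `PhysicalConstants` and can be
  overridden, e.g. for altitude.
* **Projection factor.** The coning angle θ is measured from the descent
  (spin) axis, so nutlet-down flight gives θ > 90° and cos θ < 0. The
  projected-area factor is therefore |cos θ| (`abs_cos`, default). A
  `sin` convention is available for data sets that report the coning
  angle from the horizontal plane.
* **Units.** All computation is in SI. The CSV dialect uses
  field-customary units (mg, mm, cm², m/s, rad/s, degrees), converted
  exactly at the I/O boundary; round trips are exact to 1e-12 relative.
  Angles are stored in degrees and converted to radians only inside
  trigonometric evaluation.
* **Angle of attack** is tabulated at the 0.75-span blade station:
  φ = arctan(V_d / 0.75 S ω).
* **Centrifugal force** is m ω² r_c. No axis location is implied by the
  data, so the package adopts a fixed internal convention —
  r_c = 0.25 S, the centroid path with the spin axis at the nutlet end
  (the complement of the 0.75 S blade station) — configurable via
  `r_c_fraction`. Because published force-ratio slopes depend on an
  unstated radius convention, centrifugal-force comparisons are
  meaningful within a run, not across conventions.

## Fitting machinery

* **Power laws** are fitted by ordinary least squares in log10–log10
  space, the standard allometric convention. With a free exponent, R² is
  the squared Pearson correlation in fit space; with an imposed exponent
  only the prefactor is estimated and R² = 1 − SS_res/SS_tot against the
  mean of log10 y, which can be negative. Free fits require n ≥ 3, fixed
  fits n ≥ 2. Nesting guarantees the free R² is never below the fixed
  one; the implementation is cross-checked against a normal-equations
  oracle at 1e-10.
* **Drag fits** regress the lumped force against weight on specimen
  means over replicates (each wind-tunnel observation is a triplicate);
  a `per_replicate` switch fits raw observations. The intercept is free
  by default — it is a useful diagnostic for species sitting off the
  interspecific trend — with a `through_origin` option. C_D = 2/slope in
  either case.
* **Perturbation responses** divide each dynamic quantity by its
  specimen's unaltered (level-0) value and fit the three reduced
  responses against the driver ratio. Baseline points participate in the
  fits; records flagged as failed (no stable autorotation) are excluded
  from fits but retained for the robustness extremes. Mass fits pool the
  addition and subtraction branches by default; a `kinds` argument
  restricts them.

## Morphometry

Silhouettes are segmented by Otsu's threshold (explicit override
available), keeping the largest 8-connected component and filling holes;
polarity (dark-on-light or light-on-dark) is configurable. Span is the
maximum distance between foreground pixel centres, computed on the convex
hull (provably equal to the all-pairs maximum, and tested as such); ties
are broken toward the lexicographically smallest endpoint pair for
determinism. Chord is the hull extent perpendicular to the span
direction; area is the pixel count times the squared scale. Distances are
between pixel centres, so lengths carry a ±2-pixel discretisation
tolerance and areas about 2 % at 10 px/mm; rotation changes all three
measures by under 2 % at that scale. Collinear (degenerate) silhouettes
report a one-pixel chord with a warning. The mm-per-pixel scale is
user-supplied; no ruler detection is attempted.

## The synthetic generator

The generator stands in for wind-tunnel data and encodes the population
structure the analysis assumes:

* **Geometry.** Per species, chord is lognormal (log10 sd 0.008, a
  deliberately tight intraspecific spread so that 160 specimens stay
  inside the study's reported interspecific extremes of mass
  6.3–19.1 mg, span 17.2–60.6 mm, and area 0.53–5.72 cm²); span follows
  from a chord-span ratio (0.33, 0.34 and 0.25 for *A. ginnala*,
  *A. floridanum* and *A. campestre*, as measured); area is a shape
  factor k times the span-chord box, k in 0.52–0.61.
* **Mass and coning angle are calibrated jointly.** Within the reported
  ranges, specimen masses occupy a narrow band while areas vary
  ten-fold, so mass/area ratios fall steeply with size. Each preset
  therefore specifies a calibration mass, and the generator solves the
  force balance for the coning angle at which that species' median
  specimen descends at the common target speed of 0.83 m/s — small
  dense-wing species cone far from 90°, large low-loading species cone
  close to it. This is the generator's expression of the empirical
  observation that wildly different samaras share a tight descent-speed
  band, and it makes the coning-angle term do real work in the drag fit.
* **Weighting.** The mass model is m = w · μ · A^(3/2). The weighting
  factor w is the single lever for allometric departures:
  *A. saccharum* w = 1.45 (overweighted, falls ~√1.45 faster) and
  *A. negundo* w = 0.60 (underweighted, slower); all others w = 1.
  Removing the two weighted species moves the pooled area–mass exponent
  toward the allometric 2/3, mirroring the interspecific pattern.
  A separate strictly isometric preset family (shared proportions and
  mass coefficient) exists for exact-recovery tests, where all four
  allometric exponents and the drag coefficient are recovered to
  numerical precision.
* **Dynamics.** Coning angles are truncated-normal per replicate in
  (91°, 179°); descent velocity solves the balance at the true C_D
  (default 5.99) times multiplicative lognormal noise (sd 0.05);
  angular velocity is derived through a truncated-normal angle-of-attack
  distribution (42.5 ± 3.2°) times lognormal noise (sd 0.05), so
  generated populations reproduce the tight φ band by construction.
  Velocity noise models hover-speed measurement error; the per-replicate
  coning-angle draw is the flight-to-flight variation, and the velocity
  computed from it keeps each flight physically self-consistent.
* **Perturbation series** multiply baseline dynamics by
  ratio^exponent × lognormal noise, observed in three replicates per
  level like every other trial. Default exponents: 0.12, 0.70, −0.48
  (V, ω, θ vs m/m0) and −0.79, 0.03, −0.38 (vs A/A0). Mass addition
  inflates area by at most 5 % (wax on the nutlet); subtraction leaves
  it unchanged; ablation leaves at least 96 % of mass. Failure bounds
  are per species (e.g. *A. negundo* autorotates for
  0.5 ≤ m/m0 ≤ 2.25, *A. macrophyllum* fails above 1.3; ablation
  failure thresholds fall from A/A0 = 0.80 for the smallest wings to
  0.60 for the largest); levels beyond the bounds are generated but
  flagged failed. Failure is a deterministic function of the level, not
  of the realised dynamics, so its exclusion does not bias the fits.
* **Silhouette rendering** draws a nutlet ellipse plus a tapered,
  curved-leading-edge wing as an exact polygon (the ellipse as a
  256-gon), records the polygon's analytic span, chord, area, and the
  rasterised pixel count as ground truth, and rasterises at a
  user-chosen scale (minimum 5 px/mm).

What the generator does **not** emulate: real intraspecific size
variation (deliberately compressed, see above), correlated measurement
errors between V_d and θ, any mechanistic model of autorotation onset or
failure (bounds are imposed empirically), nutlet/wing mass distribution,
and silhouette texture such as trichomes. Passing recovery tests
therefore demonstrates that the estimators are unbiased and correctly
implemented under the assumed noise structure, not that real data meet
those assumptions.

## Monte-Carlo test sizing

Recovery bands were sized by an a-priori power analysis of the log-space
regression standard error. The ablation-response fit is the tightest
case: its driver spans only 0.19 decades, so at 12 specimens × 5 levels
the exponent's sampling sd is ≈ 0.03 even with triplicate flights. The
±0.04 Monte-Carlo recovery tests therefore use cohorts sized so the
standard error is roughly a third of the band: 24 specimens for mass
series and 96 for ablation series, 200 seeded replicates each. The
single-run acceptance computations use the study-scale design of 12
specimens (3 per perturbed species).

## Numerical notes and known limitations

* Degenerate inputs raise typed errors (`SingularFitError` for spreadless
  regressors, `NoEquilibriumError` at θ = 90°, `MissingBaselineError` for
  series without an unaltered record) naming the offending quantity.
* Reduction is idempotent; baseline ratios are forced to exactly 1 to
  avoid 1-ulp noise.
* The pooled area–mass exponent of the default population is strongly
  negative, not 2/3: with mass nearly flat across species and area
  varying ten-fold, the log–log regression of A on m is dominated by
  scatter, and the weighted species push it further from the allometric
  prediction. This is a property of the emulated population structure,
  not of the fitting code (the isometric presets recover 2/3 exactly).
* Bootstrap confidence intervals are not provided; the fits report R²
  and n only.
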
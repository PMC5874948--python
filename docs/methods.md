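# Methods

## The problem

Pre-treatment patient-specific QA for fixed-beam IMRT compares a calculated
dose distribution with a measurement (diode array or EPID portal dosimetry)
using the gamma index, and reports the percentage of evaluated points with
gamma ≤ 1.  `virtualqa` models that passing rate directly from the plan:
apertures that are small, irregular, heavily modulated, or dominated by
penumbra and low-fluence regions are harder to deliver and to measure, and
fail more points.  Predicting the passing rate from plan geometry lets a
planner flag likely-failing plans before anything is measured.

## Statistical model

A QA unit (a composite plan or a single beam, depending on how the QA
programme measures) is summarised by a feature vector `x` with `x₁ = 1`.
With `D` evaluated detectors and `y` failing, the model is

    y ~ Poisson(D · fr(x)),      fr(x) = exp(βᵀx)

where `fr` is the failing rate (1 − passing rate/100).  The coefficients are
the maximum a-posteriori estimate under a zero-mean Laplace prior, i.e. the
minimizer of the weighted, L1-penalized negative log-likelihood

    L(β) = − Σᵢ wᵢ ( frᵢ βᵀxᵢ − exp(βᵀxᵢ) ) + λ Σ_{j≥2} |βⱼ|

with observed rates `frᵢ = yᵢ/Dᵢ` and weights `wᵢ = Dᵢ/D_max`: a unit
measured with more detectors carries proportionally more information.
`D_max` is fixed at training time and serialized with the model so
prediction-time behaviour is reproducible.

Conventions this package fixes (the model statement alone does not):

* the intercept is not penalized — penalizing it would make the strong-
  shrinkage limit degenerate rather than the weighted mean rate;
* λ multiplies the L1 norm directly (prior scale and penalty weight are
  reciprocal under the Laplace parameterisation; we use the penalty form);
* non-intercept columns are standardized internally to weighted mean 0 /
  variance 1 before penalization, so indicator and continuous features are
  penalized comparably; coefficients are reported on the original scale;
* perfectly passing units (`fr = 0`) are kept as-is: their `y log μ` term is
  zero and no pseudo-count is added;
* predicted `fr` is clipped at 1 only when converted to a passing rate for
  presentation; the raw exponential value is preserved.

### Solver

Cyclic coordinate descent with soft-thresholding on the iteratively
reweighted least-squares quadratic approximation (the standard penalized-GLM
scheme): outer IRLS loop with working weights `wᵢμᵢ`, inner coordinate
sweeps with active-set cycling, warm starts along a log-spaced λ path from
`λ_max` (the smallest λ with empty selection, computed in closed form from
the intercept-only solution) down to `λ_max · 10⁻⁴` over 100 values by
default.  A step-halving safeguard keeps the objective non-increasing when
the quadratic approximation overshoots.  Convergence is declared at relative
objective change below 1e-8 (budget 1e5 sweeps; non-convergence is flagged,
not raised).  Every fit can be certified by a KKT report: zero coefficients
must have |score| ≤ λ, nonzero ones must satisfy stationarity.

Model selection uses K-fold cross-validation (default 10-fold) on mean
weighted Poisson deviance, reporting both `lambda_min` (used by default) and
`lambda_1se`.  Separate models per energy/QA-device stratum are enforced
unless explicitly overridden, since delivery systems respond differently.

## Complexity features

Geometry is computed on a 1 mm binary raster of each control point's
aperture at the isocenter plane (pixel open iff its center lies strictly
between the leaf tips of its pair and inside the jaw rectangle).  The 1 mm
default is finer than any leaf width or detector pitch at negligible cost.

Per-control-point scalar metrics (gap fractions, aperture area/perimeter,
shape irregularity) are averaged with trapezoidal ΔMU weights — each control
point carries half the MU of its adjacent intervals — while fluence
accumulation uses the step-and-shoot convention (each interval exposed
through its starting aperture; a `mid` mode averaging interval endpoints is
available for sliding-window deliveries).

The metric families:

* **CIAO area / perimeter** — union of all apertures; perimeter via
  marching-squares contours of the Gaussian-smoothed (σ = 1.5 px) indicator,
  which converges at O(spacing) on both polygonal and curved shapes (plain
  binary contours converge to a staircase limit ~5% high on curved
  boundaries; thin apertures that smoothing would erase fall back to the
  binary contour);
* **small-aperture scores** — ΔMU-weighted fraction of counted leaf gaps
  below 2/5/10/20 mm.  A gap is counted when it exceeds 0.5 mm (parked
  closed pairs are excluded — without this the park position dominates) and
  its pair midline lies inside the jaw y-opening.  A beam with no counted
  gaps ever gets score 0 plus an explicit `small_aperture_undefined` flag;
* **fluence-level fractions** — area at ≥10/20/30/40/50% of the peak
  accumulated fluence, normalised by the ≥10% area (mirroring the 10%
  measurement threshold), plus the "less than" complements;
* **irregularity** — fraction of CIAO area beyond 5/10/20 cm of the central
  axis, and the ΔMU-weighted isoperimetric quotient P²/(4πA) (1 for a disc);
* **penumbra fraction** — ΔMU-weighted fraction of aperture area within
  5 mm (configurable) of the aperture edge, computed by Euclidean distance
  transform;
* **duty cycle** — total MU per cGy of prescribed fraction dose;
* **modulation factor** — ordinal 1/2/3 from duty-cycle cuts at 3 and
  5 MU/cGy by default, overridable per unit;
* **categorical context** — QA device, energy, machine type, MLC model.

### Encoding

The default feature vector has 91 entries: the intercept, one-hot groups for
the categorical context and modulation level, Table-style one-hot bins for
CIAO area (<5…>30 cm²), jaw opening (<5…>25 cm, binned on the larger of the
x/y extents), perimeter (<10…>110 cm) and duty cycle (<2…>6 MU/cGy) — each
binned family also enters continuously — the fraction metrics above as
continuous values, ΔMU-weighted gap and aperture statistics, and three-level
(low/mid/high at 1/3, 2/3) categorical companions for the six fraction
metrics most associated with failing plans (the four small-aperture scores,
the <50% fluence-area fraction, and the penumbra fraction).  Binning is
left-closed/right-open with open-ended extremes so printed edge values land
deterministically.  Plan-level vectors aggregate per-beam continuous metrics
MU-weighted *before* binning; beam-level vectors use the owning plan only
for prescription/QA-device context.  The encoding is a pure function of
(input, config), and a hash of the config travels with every feature table
and model so mismatched encodings are refused at predict time.

## Gamma engine

For each reference pixel at or above the dose threshold (default 10% of the
reference maximum), gamma is the minimum over displacements `r` within
3×DTA of

    sqrt( (D_eval(r) − D_ref)² / tol²  +  |r|²/DTA² )

with `tol` = dose_pct% of the local reference dose (local normalization, the
default) or of the global maximum.  The evaluated grid is sampled by
bilinear interpolation on a displacement lattice of pitch DTA/10 by default;
displacements are visited in increasing radius and the search stops once the
distance term alone exceeds every pixel's current best gamma (this pruning
is exact).  The lattice pitch is configurable: a pitch that divides an
expected rigid shift makes "DTA absorbs the shift" hold exactly, and holding
the pitch fixed while loosening the criterion makes the loose lattice a
superset of the tight one, so passing rates are provably monotone under
loosening.  Local normalization at very low dose is intentionally harsh;
a low-signal screen (`low_signal_flag`) flags beams whose above-threshold
mean CU falls below a configurable cutoff, where EPID response differences
make measured gamma unreliable — no EPID response correction is attempted.

## Synthetic data

The generator draws data from the model's own generative story so ground
truth is known exactly.  Defaults describe a per-beam portal-dosimetry QA
programme: mean failing rate 3% (typical QA passes ≈97%), six true effects
of magnitude ≈0.5 on the log rate (per-unit failing rates spanning roughly
1–10%), 700–1700 evaluated pixels per unit, and Poisson counts truncated at
the detector count (a rate per detector cannot exceed 1).  The intercept is
calibrated so the mean true failing rate equals the target exactly.  An
overdispersion knob (gamma-mixed Poisson with variance/mean equal to the
knob) is available; the default is pure Poisson.

`abstract` mode draws feature vectors directly — five one-hot groups (sizes
2, 5, 3, 7, 6) plus 67 uniform continuous metrics, p = 90.  True one-hot
effects are placed only on the 5-level group: a single-dummy effect in a
2-level group is not identifiable under L1 (it can be absorbed into the
intercept and the complementary dummy at equal penalty cost).  `geometric`
mode generates physically valid beams — monotone MU fractions, non-negative
gaps, jaws enclosing apertures, a modulation knob that monotonically shrinks
typical leaf gaps — and runs the real feature pipeline.

What the generator does **not** emulate: spatially correlated failure
regions, detector-array geometry, EPID response nonlinearity, setup error,
machine drift, or any dependence of measurement noise on dose level.
Passing tests therefore demonstrate the statistical machinery and geometric
code, not clinical accuracy on any institution's data; a clinical deployment
must train on its own measured QA history, per energy and device.

## Evaluation experiments

Residuals are *predicted minus measured* passing rate in percentage points.
The learning curve subsamples training sets without replacement (seeded),
selects λ by CV within each subset, and evaluates mean absolute residual on
the subset and on the untouched remainder; 95% confidence intervals are
t-based across repetitions (default 10).  The reported plateau is the first
size whose mean test error is within one CI half-width of the largest
size's.  Note a property of CV-selected regularization: at very small
training sizes CV chooses heavy shrinkage, so *training* error can be
highest at the smallest size — the classic low-training-error signature of
overfitting appears only at fixed λ.

## Problem sizes used in the checks

The shipped acceptance script and test suite use: n = 200 (p = 10) for
solver-oracle agreement, n = 1000 train / 300 test (p = 90) for recovery and
out-of-sample accuracy, grids ≤ 25×25 for exhaustive gamma comparison, and a
400-unit study with sizes 30–240 and 10 repetitions for the learning curve.
These sizes were chosen to exercise every code path at desk scale.

## Known limitations

* Fixed-beam IMRT only; VMAT delivery metrics (gantry/leaf speed) are out of
  scope.
* No interaction terms between features.
* Leaf transmission and tongue-and-groove effects are represented only
  categorically (MLC model), not physically.
* The gamma engine is 2D with rigid-lattice search; no automatic
  registration.
* Perimeter-based metrics underestimate slightly for apertures thinner than
  ~2 pixels (smoothing fallback).
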
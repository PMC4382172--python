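# Methods

This note records the models, parameter choices and numerical conventions
behind `ovicolor`, and what its synthetic data do and do not establish.

## Spectral preprocessing

Curves live on a working grid of 300–700 nm at 1-nm steps (configurable).
Replicate reflectance measurements are averaged as a flat pointwise mean
over all replicates; for the balanced nine-reading design (three readings
at each of blunt pole, middle, sharp pole) this equals the mean of
per-position means. Regridding is linear interpolation with no
extrapolation; sensitivity curves digitized from 330 nm upward are
extended to 300 nm with zeros (`pad_sensitivity`), the standard convention
when ultraviolet tails are unavailable.

Smoothing uses a symmetric triangular kernel whose **total base width**
is the nominal width (default 30 nm, i.e. half-width 15 nm); the kernel is
renormalized to unit local mass at the boundaries. Consequences used as
test oracles: constants and interior affine ramps pass through unchanged,
the integral of an interior-supported spectrum is conserved to 1e-9, and
output never leaves the input's range. A width under two grid steps
cannot smooth and returns the input with a warning. The kernel convention
is configurable because smoothing conventions differ between
spectrometry packages.

Reflectance units are auto-detected: any value above 2 means percent, and
the curve is divided by 100; an override flag exists because genuinely
super-unity proportional reflectance (gloss) would be misclassified.

## Visual model

Quantum catches are rectangular sums Q_i = Σ R·I·S_i·Δλ at 1 nm
(trapezoid differs negligibly at this resolution and step). The
achromatic channel is the MWS+LWS sensitivity sum, a proxy for the
double-cone/rod luminance pathway. No von Kries adaptation step is
applied: both members of every comparison share one illuminant, so any
per-receptor multiplicative adaptation cancels in the log contrasts that
the chromatic distance is built from. Raw catch magnitudes therefore
depend on illuminant scaling and are reported but not interpreted.

Receptor noise: ω_i = w·sqrt(η_ref/η_i) with Weber fraction w = 0.1 and
relative densities (UVS, SWS, MWS, LWS) = (1.0, 1.78, 2.21, 1.96). The
reference cone — whose noise equals w exactly — defaults to LWS, the most
abundant class here and the dominant anchoring convention in the
receptor-noise literature. The choice is configurable because switching
the reference multiplies every ω_i, and hence divides every ΔS, by one
global constant: absolute JND magnitudes depend on it, rank orders do
not. The achromatic Weber fraction defaults to 0.1 as well and is
independently configurable.

The tetrachromatic ΔS uses the explicit four-receptor closed form.
Properties verified by tests: ΔS is a pseudometric on catch space,
invariant to uniform intensity scaling of either spectrum, and collapses
exactly to the dichromatic form |Δf_x−Δf_y|/sqrt(ω_x²+ω_y²) when two
receptor pairs are degenerate (a duplicated channel pools noise by
1/sqrt(2), so degenerate copies at sqrt(2)·ω reproduce a single channel
at ω).

## Clutch-variation analysis

Proportional catches Pr_i = Q_i/ΣQ_j (single cones only) are the per-egg
responses; each is tested across clutches, as is the achromatic catch.
"ANOVA across clutches" is implemented as **Welch's heteroscedastic
one-way test** — grouped color data routinely violate homoscedasticity,
and the Welch statistic's non-integer denominator df is the appropriate
reference distribution. The classical equal-variance ANOVA is available
(`classic_oneway`) for comparison. The Welch implementation follows the
standard weighted formulation and is cross-checked in tests against an
independent implementation (pingouin) and against the squared Welch t for
k = 2. Clutches with fewer than two eggs are excluded from across-clutch
tests (a variance per group is required) and the exclusion is recorded in
the report; a zero-variance group raises rather than silently producing
an infinite F.

To compare within- vs between-clutch discriminability without
pseudoreplication, all pairwise JNDs are computed and then thinned to a
random set of comparisons in which each egg appears once
(`sample_disjoint_pairs`, a seeded uniformly random greedy maximal
matching; floor(e/2) comparisons for e eggs, the odd egg dropped and
reported). For report purposes the matching is **stratified and
balanced** (`within_first=True`): within-clutch pairs are drawn first, up
to half of the final comparisons, and remaining eggs are paired across
clutches. Rationale: with many small clutches a fully uniform matching
contains almost no within-clutch pair (expected ≈ 1 for 23 clutches of
3), leaving the within/between contrast undefined, and equal allocation
maximizes the power of the two-group Welch comparison. The purely
uniform matching remains the default of the standalone function.

No multiple-testing correction is applied across the report's six tests,
matching the presentation of such analyses as independent univariate
questions.

## Rejection-experiment statistics

The 3×2 (IV/DV/UNM × reject/accept) table is tested with Fisher's exact
test by **full enumeration** of margin-fixed tables under the
multivariate hypergeometric null, using the probability-ordering
two-sided rule (sum the probabilities of all tables no more probable
than the observed one, with a 1e-7 relative tie tolerance). Enumeration
is refused above N = 200; the Monte-Carlo version samples margin-fixed
tables (Patefield's algorithm via scipy, distributionally identical to
permuting column labels against row labels) and uses the add-one
estimator p = (1+B)/(replicates+1), which never returns zero; default
2000 replicates, seed-controlled. Tests verify agreement with scipy's
2×2 exact test, a frozen r×c reference value from R's `fisher.test`, and
MC-vs-exact convergence within Monte-Carlo error.

Effect size is Cramér's V = sqrt(χ²/(N·(min(r,c)−1))) from the
uncorrected Pearson χ²; for any r×2 table V equals Cohen's w. Power is
the upper tail of the noncentral χ²(df, ncp = N·w²) above the central
(1−α) quantile, so power at w = 0 is exactly α; required sample size is
a Brent root-solve of the continuous relaxation, reported both unrounded
and rounded up. The default df = 2 reflects the 3×2 design.

The binomial logistic GLM regresses rejection (1) vs acceptance (0) on
treatment (reference level DV, so reported contrasts are IV and control),
nesting stage (laying = 0, incubation = 1), Julian date, clutch size, and
year as a nominal fixed effect (a single-year data set contributes no
column, and the fit provably equals the model without year). Fitting is
Newton/IRLS with step-halving — the deviance is non-increasing by
construction — converging on relative deviance change < 1e-8 within 100
iterations; Wald z and two-sided p per term. Complete separation is
detected (pinned fitted probabilities with diverging coefficients) and
flagged with coefficients withheld rather than reported at absurd
magnitudes. The implementation is cross-checked against statsmodels'
GLM in the test suite. A year random effect (GLMM) is deliberately out
of scope; the fixed-effect model is the supported verification route.

## Synthetic data

`simulate_egg_spectra` emulates immaculate blue-green eggs as
baseline + one Gaussian reflectance peak whose center (hue) carries the
biological signal: clutch centers ~ N(500 nm, σ_B²), egg centers within a
clutch ~ N(clutch center, σ_W²), plus additive replicate measurement
noise. Defaults — 23 clutches × 3 eggs × 9 replicates, baseline 0.10,
peak height 0.45, peak width 60 nm, σ_B = 6 nm, σ_W = 2 nm, noise SD
0.01 — mirror a single-season field study of a blue-green-laying host:
most hue variance between females, a few nm within a clutch, and ~1%
spectrometer noise. Real eggshell spectra differ in ways that do not
matter for exercising the pipeline but do matter scientifically: they
carry a UV shoulder and pigment-specific curvature, and their
within-clutch covariance is not purely a hue shift. Passing tests on
synthetic data therefore demonstrate the *statistical machinery* —
variance partitioning, calibration, power — not species-level JND values.
Reproducing published JND magnitudes additionally requires the actual
measured spectra, digitized cone sensitivities for the study species and
the field irradiance spectrum, all loadable as delimited text; absolute
JNDs also depend on the reference-cone convention (above), while the
within < between ordering does not.

`simulate_sensitivities` builds cone curves from λmax values (defaults
373/454/504/557 nm, a UVS-type turdid complement) using either the
standard A1 visual-pigment nomogram (α and β bands) or a Gaussian shape,
peak-normalized, optionally zeroed below 330 nm to emulate digitized
data. `simulate_outcomes` draws independent Bernoulli outcomes per arm;
defaults (13/14/30 nests, p = 0.58 everywhere) encode a no-effect
experiment at a realistic scale with an intermediate baseline rejection
rate. All generators are bit-reproducible from their seeds.

## Problem sizes and determinism

The test suite and the acceptance script regenerate all inputs at run
time at the study's own scale (≤ 23 clutches, ≤ 2000 nests for parameter
recovery); Monte-Carlo checks use 10⁵ Fisher replicates and 10³ Welch
null replicates, sizes at which Monte-Carlo error is far below the
tolerances being asserted. Every stochastic component takes an explicit
seed; pipeline runs write a provenance block (config hash, seed,
version) so reports are byte-reproducible.

## Known limitations

- Single-peak reflectance model (no UV shoulder, no pigment chemistry).
- No ocular-media or double-cone spatial modeling; the achromatic channel
  is a sensitivity sum, not a fitted luminance mechanism.
- Absolute JND values depend on the reference-receptor and achromatic
  Weber conventions, which published analyses do not always state.
- Exact r×c Fisher enumeration is exponential in table size; beyond
  N = 200 only the Monte-Carlo route is offered.
- The logistic model assumes independent nests; shared-female or
  shared-site dependence would require the out-of-scope mixed model.
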
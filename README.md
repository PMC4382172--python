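# ovicolor

Avian-perceptual analysis of eggshell color variation, and the statistics
of artificial-parasitism egg-rejection experiments.

Hosts of avian brood parasites often defend themselves by ejecting foreign
eggs from the nest. Whether the amount of color variation *within* a
female's own clutch helps or hinders that decision is a central question in
the evolution of egg recognition. Answering it requires two things this
package provides to behavioral and sensory ecologists:

1. **A receptor-noise-limited model of tetrachromatic (UVS/SWS/MWS/LWS)
   avian vision** applied to reflectance spectra of eggs, quantifying how
   discriminable two eggs are *to a bird* in just-noticeable-difference
   (JND) units, and whether egg color varies more between clutches than
   within them.
2. **The inference toolkit for a three-arm egg-rejection experiment**
   (increased variation IV / decreased variation DV / unmanipulated UNM):
   exact and Monte-Carlo Fisher tests, Cramér's V, noncentral chi-square
   power analysis, and a binomial logistic GLM with covariates.

A synthetic-data module generates clutch-structured spectra, template cone
sensitivities and outcome tables with the same statistical structure as
field data, so the entire pipeline runs and is tested without downloads.

## The model

Quantum catch of cone class *i* for an egg with reflectance *R*(λ) under
irradiance *I*(λ), with cone sensitivity *S<sub>i</sub>*(λ), integrated over
300–700 nm:

    Q_i = Σ_λ R(λ) I(λ) S_i(λ) Δλ

The achromatic (luminance) catch uses the summed MWS+LWS sensitivity.
Receptor noise follows a Weber fraction *w* anchored on the reference cone
and scales with relative cone density η<sub>i</sub>:

    ω_i = w · sqrt(η_ref / η_i)

With log catch contrasts Δf<sub>i</sub> = ln(Q<sub>i</sub><sup>a</sup>/Q<sub>i</sub><sup>b</sup>),
chromatic discriminability ΔS is the tetrachromatic receptor-noise
distance (see `ovicolor.visual.chromatic_jnd` for the closed form); the
achromatic contrast is ΔL = |Δf<sub>A</sub>|/w<sub>A</sub>. ΔS > 1 JND is
conventionally discriminable. Defaults: densities
(UVS, SWS, MWS, LWS) = (1.0, 1.78, 2.21, 1.96), *w* = 0.1, reference LWS.

Spectra are preprocessed by replicate averaging (nine probe readings per
egg), linear regridding to a 1-nm working grid, and 30-nm triangular
smoothing. Proportional catches Pr<sub>i</sub> = Q<sub>i</sub>/ΣQ<sub>j</sub>
per egg are compared across clutches with Welch's heteroscedastic one-way
test; JNDs from a single-use random pairing of eggs are compared within vs
between clutches the same way.

## Worked example

Run everything on synthetic data (23 clutches × 3 eggs × 9 replicate
spectra; 57 experimental nests):

```sh
ovicolor run-all --synthetic --seed 1 --outdir demo
```

`demo/variation_report.tsv` (abridged):

```
response     mean      se       df1  df2      F        p
PrUVS        0.0779    0.0005   22   16.60    42.56    1.2e-10
PrSWS        0.2544    0.0011   22   16.51   107.48    7.5e-14
...
ChromJND_W   0.1686    0.0294    1   17.45    16.16    8.5e-04
ChromJND_B   0.7357    0.1380    1   17.45    16.16    8.5e-04
```

Each `Pr` row is a Welch one-way test of that cone's proportional catch
across clutches (here strongly significant: the generator's default puts
most hue variance between clutches). The last two rows compare mean
chromatic JNDs for within-clutch (W) vs between-clutch (B) single-use egg
pairs: between-clutch pairs are ~4× more discriminable, and the two-group
Welch test rejects equality (p ≈ 8×10⁻⁴) — eggs of different females look
more different to a bird than eggs of one female.

`demo/power_report.tsv`:

```
chi2     cramers_v  df  N   power     required_n
3.289    0.2402     2   57  0.349     167
```

With no true treatment effect simulated, the 3×2 Fisher test is
non-significant (`demo/fisher.tsv`: p_exact = 0.22, p_mc = 0.22 at 2000
replicates), the observed effect size is small, the experiment's power at
N = 57 is 0.35, and 167 nests would be needed for power 0.8 at that
effect size. `demo/glm_coefficients.tsv` holds the logistic-regression
coefficients (log-odds of rejection) for treatment contrasts against the
DV reference, nesting stage, Julian date, clutch size and year.

## Scope notes

Recognition cognition is outside the computational scope, but frames the
experiment the statistics serve: hosts may recognize foreign eggs by
*discordancy* (reject the minority egg type), by a memorized *template* of
their own eggs, or by *online self-referent comparison* with their own eggs
in the current clutch. For hosts of a **non-mimetic** parasite all three
mechanisms predict **no effect** of experimentally increasing or decreasing
intraclutch color variation on rejection, whereas for hosts of mimetic
parasites discordancy and self-referent mechanisms predict reduced
rejection under increased variation. The package's rejection statistics
are the machinery for testing exactly these predictions.

Not implemented by design: spectrometer calibration arithmetic,
ocular-media transmittance, daylight models, mixed (random-effects)
models, and maculation/pattern analysis.
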
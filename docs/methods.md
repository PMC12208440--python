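# Methods

This note documents the models, numerical choices and limitations behind
`melanosub`. Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`.

## Spectral model

All optics live on a uniform wavelength grid, 380–780 nm in 1 nm steps
(Δλ = 1). A spectral power distribution (SPD) is a non-negative radiance
vector in W·sr⁻¹·m⁻²·nm⁻¹; receptor excitations are discrete sums
E_p = Σ S(λ)·R_p(λ)·Δλ, and luminance is Y = 683·Σ S(λ)·V(λ)·Δλ in cd/m².

### Sensitivity functions

No tabulated standards are shipped; every weighting function is analytic:

- **Colour-matching functions** x̄, ȳ, z̄: the multi-lobe piecewise-Gaussian
  fits of Wyman, Sloan & Shirley (2013) to the CIE 1931 2° CMFs, clipped at
  zero and rescaled so (i) the three integrals are equal — an equal-energy
  spectrum maps to xy = (1/3, 1/3) exactly — and (ii) the ȳ peak is exactly
  1, so ȳ doubles as V(λ) and the colorimetric and photometric transforms
  share one luminance scale.
- **Cone fundamentals** L, M, S: a fixed invertible 3×3 transform of the
  CMFs, starting from the Hunt–Pointer–Estévez matrix with each negative
  entry shrunk (binary search) to the largest magnitude that keeps the
  fundamental non-negative on the grid, then peak-normalised. This is the
  classical construction of fundamentals as CMF combinations
  (Smith–Pokorny style). Its payoff is algebraic: **two spectra with equal
  tristimulus values have exactly equal cone excitations**, which makes
  cone silencing in the metamer solver exact rather than approximate.
- **Melanopic and rhodopic sensitivities**: the Govardovskii et al. (2000)
  A1 opsin alpha-band template at the retinal pigment peak (480 nm for
  melanopsin, 496.3 nm for rhodopsin), multiplied by an analytic lens
  transmission model D(λ) = 1.7·exp(−(λ−400)/32) (optical density), and by
  λ/λmax to convert quantal to energy units. No macular pigment is applied
  (ipRGCs and rods are parafoveal). The lens scale/slope were set so the
  corneal melanopic curve reproduces the standard alpha-opic anchor
  mel(450 nm) ≈ 0.41 of peak; the resulting corneal peaks are ≈ 493 nm
  (melanopic) and ≈ 507 nm (rhodopic, the scotopic peak).

These analytic stand-ins deviate from the tabulated standards by a few
percent. That is the appropriate fidelity here: the projector primaries are
themselves synthetic, and every quantitative claim the package makes is
evaluated against its own functions, self-consistently.

### CIELAB

Standard forward/inverse transform with the (6/29)³ branch point. The
default white is the equal-energy chromaticity scaled to the high light's
luminance, so the high light sits at L\* = 100. Candidate geometry is
expressed as **offsets** in this a\*b\* plane, never as absolute a\*b\*
positions: published absolute coordinates for such stimuli depend on an
unstated white-point scaling, and offsets are invariant to it.

## The synthetic rig

Two three-channel projectors superimpose on one diffuser, so a displayed
light is a non-negative mixture of six primaries, each a sum of Gaussian
emission bands with an optical filter:

- projector A ("cyan-capable"): R and G are single dominant bands with a
  weak secondary; B is a ~450 nm band (σ = 13 nm) **plus an additive
  488 nm line** with the 10 nm-FWHM shape of a bandpass filter in a
  beam-split blue path. A purely multiplicative narrow bandpass would
  confine the channel to the line and contradict its deep-blue published
  chromaticity, so the additive reading is the physically coherent one.
- projector B ("S-cone"): all channels behind a 435 nm long-pass
  (sigmoidal cut-on, ~4 nm transition); its blue is a ~455 nm band plus a
  broad long-wave leak.

Each channel's free parameters are fitted by least squares to its target
CIE xy. The fits are **exactly identified** — two free parameters (band
centre + secondary/line fraction) against the two chromaticity
coordinates, with emission widths fixed at typical 3LCD bandwidths — so
quantities that matter scientifically (e.g. the cyan-line fraction) are
determined by the chromaticity targets, not by optimizer initialisation.
Fits failing the 0.01 xy tolerance raise a convergence error naming the
channel. Channel amplitudes are then scaled to per-channel maximum
luminances (R 600, G 2000, B 300 cd/m² — screen-luminance proportions of a
bright 3LCD projector; they only define the feasible box and were verified
not to bind the default solve).

## Metamer solving

With target chromaticity (x, y) and luminance Y, both pair members are
pinned to the same tristimulus vector and to equal cone excitations, and
the melanopic difference is maximised over the 12-dimensional weight box
via one linear program (HiGHS; rows scaled to unit max for conditioning).
Because LMS is an exact transform of XYZ, the cone-silencing rows are
implied by the tristimulus rows and the LP is never over-determined; the
solved pair satisfies chromaticity and luminance exactly and cone
silencing at machine precision (residual ~1e−16, far below the 1e−6
contract). Infeasible targets raise a gamut error reporting the achievable
luminance range at that chromaticity.

The default solve at (0.412, 0.241), 713.56 cd/m² yields a melanopic
Michelson contrast of ≈ 18.3%. Constraint-relaxation analysis shows what
binds it: dropping the chromaticity pin (keeping cone silencing and
luminance) raises the ceiling only to ≈ 18.6%, dropping S-cone silencing
changes nothing, while releasing L/M silencing would allow ≈ 97% — so the
limit is the L/M-cone match given these surrogate spectra. An in-vivo rig
with measured spectra (and a chromaticity chosen at *its* optimum) can sit
several points higher; contrasts in the low-to-mid 20s are the regime such
rigs report.

Candidates: rings in a\*b\* (default 1 centre, 4 at radius 1, 7 at radius
3; angles equally spaced from a seeded random phase, distances exact).
Each candidate keeps L\* fixed (hence the centre luminance), converts back
to xy, and is solved as the *minimal*-melanopic light there. Whether such
candidates should instead be full cone-metamers of the high light is
under-determined by the protocol being emulated; the minimal-melanopic
reading is the default and the solver accepts any target.

Rod (rhodopic) excitation is computed and reported but never constrained.

## Observer models

- **Tuning**: perceived difference = a\*b\* distance + N(0, σ) noise,
  "identical" iff below a threshold ΔE. Defaults σ = 0.75, ΔE = 1.5 make
  the centre and radius-1 candidates plausibly confusable and radius-3
  candidates mostly discriminable. Selection = argmax "yes"; ties break by
  CIE-xy distance to the high light, then lowest id (deterministic).
- **Brightness**: B = Y·(1 + g·C/100) with C the light's signed melanopic
  contrast about the pair mean. The staircase steps the matching light's
  luminance (default 5 cd/m²) until the perceived ordering flips; the
  closed-form match ratio is (1 + gC/100)/(1 − gC/100). The default gain
  g = 0.5 makes the high light ≈ 20% brighter at the default rig's
  contrast, the magnitude such melanopsin brightness-enhancement
  experiments report; `gain_for_enhancement` computes g for any target.

## Behaviour generator

Study layout: 26 subjects (13 starting with the high light — even subject
indices), 2 blocks (one per light), 6 runs × (50 one-back + 50 two-back
trials), trial = 0.5 s letter + 1.5 s ISI, 16-letter alphabet. Target
rate 0.3 of eligible positions (exact count, positions seeded); the rate
and the 150–2000 ms response window are conventions of this generator,
stated in config. Hits/false alarms are Bernoulli per trial; RTs are
truncated normal. Ratings follow intercept + slope·run + light effect +
noise, clipped to 0–10. Pupil traces are 1 kHz AR(1) (lag-1 = 0.995)
around baseline + 0.2 mm two-back dilation − 0.3 mm high-light
constriction, with Poisson blinks as exact zero runs (0.2 Hz, 150 ms) and
a pixel channel at 13 px/mm. Between-subject heterogeneity perturbs
baselines and the pupil effect sizes (sd 0.08 mm); base probabilities are
clipped to leave headroom for additive effects, so injected effects are
never silently truncated.

Default injected effects: +0.06 two-back hit probability, −0.015 two-back
false-alarm probability, −18/−4 ms RT (1-/2-back), −0.5/−0.8 rating points
(sleepiness/fatigue) under the high light. These magnitudes make a
26-subject cohort detect the light × N-back interaction in roughly 8 of 10
replicates — a realistically powered, not saturated, regime.

What the generator does *not* emulate: sequential dependencies in
responses, RT–accuracy coupling, pupil event-locked dynamics (only level
shifts), gaze. Passing recovery tests therefore validates the analysis
chain's correctness and calibration, not its robustness to those
real-data features.

A binomial fast path (`cohort_hit_rates`) draws per-cell hit counts
directly — distributionally identical to aggregating the trial-level
Bernoulli model — and is what the replication-heavy calibration tests use
(1,000 null cohorts, 200 effect cohorts) to stay fast.

## Pupil preprocessing

Blinks are exact zeros; outliers are samples beyond mean ± 2.576·sd
(the 99% normal-theory interval) computed once over all valid samples of
the whole recording per participant — no iteration, since re-applying the
rule to cleaned data would re-flag ~1% forever. Masked runs are replaced
by monotone PCHIP anchored at the nearest valid neighbours (never
overshooting them, unlike Catmull–Rom); leading/trailing gaps take the
nearest valid value; unmasked samples pass through bit-exactly; cleaned
traces carry a flag making the operation idempotent. An alternative
reading computes the interval before blink removal; with zeros included
the interval collapses toward the blink mass, so the blink-removed
variant is the default. Eye selection for two-eye recordings: fewer
masked samples wins, ties to the left eye. Aggregation averages cleaned
millimetre samples over task periods per subject × task × light.

## Statistics

- **2×2 RM-ANOVA**: textbook within-subject decomposition, each effect
  tested against its effect-by-subject interaction; ηp² =
  SS_effect/(SS_effect+SS_error). With two levels per factor, sphericity
  is vacuous (ε ≡ 1); the generalised one-way k-level variant runs
  Mauchly's W (orthonormal-contrast covariance) and applies
  Greenhouse–Geisser ε to both df when Mauchly's p < .05.
- **Paired t / d_z**: d_z = mean(d)/sd(d), so d_z·√n = t. (Published d_z
  values sometimes disagree with this identity; the standard definition is
  implemented.)
- **Holm** step-down for the "modified Bonferroni" multiple-comparison
  correction — the most common referent of that phrase; an interpretation,
  flagged as such.
- **JZS Bayes factor**: the one-sample form with inverse-χ²(1) prior on g
  (Cauchy prior scale r = √2/2 on effect size, configurable), integrated
  in log space with the substitution g = u/(1−u) by adaptive quadrature
  (rel. tol 1e−10, convergence enforced at 1e−6). Agrees with an
  independent implementation to <0.1% and reproduces reference values at
  n = 26 (e.g. t = 2.728 → 4.20).
- **Mixed models**: REML random-intercept fits via statsmodels MixedLM.
  Percentile bootstrap CIs (default 10,000 resamples, seeded) resample
  subjects; the bootstrap statistic is the within-subject demeaned OLS
  slope, which equals the mixed-model fixed effect for balanced
  random-intercept data and keeps the resampling O(subjects) via
  per-subject sufficient statistics.
- **Mediation**: X coded 0/1, M and Y z-scored once on the full sample;
  a from M~X, b and c′ from Y~X+M; indirect = a·b with percentile
  bootstrap CI over resampled triples; p-values are normal approximations
  from the bootstrap sd. Null coverage of the indirect CI is verified at
  ≥ 94% over 500 simulated datasets.
- **Power**: within-factors convention λ = N·f²·(m/(1−ρ))·ε, df1 = (m−1)ε,
  df2 = (N−1)(m−1)ε; the minimum N is the smallest integer whose
  noncentral-F tail power reaches the target (N = 24 at f = 0.3, α = .05,
  power = .8, m = 2, ρ = .5).

## Reproducibility and problem sizes

Every stochastic routine takes an explicit seed; pipeline stages derive
seeds as SHA-256(master seed : stage name), and identical configs
reproduce identical output hashes. The default full pipeline (26 subjects,
1 kHz pupil) completes in about a minute on one CPU. Calibration suites
use 1,000 null simulations (type-I error), 500 datasets × 1,000 bootstrap
resamples (mediation coverage) and 200 replicate cohorts (interaction
recovery) — sizes chosen so binomial noise on the checked proportions is
well inside the asserted bands.

## Known limitations

- The spectral functions are analytic approximations; absolute colorimetry
  (e.g. exact spectral-locus coordinates) deviates slightly from the
  tabulated standards.
- The solved melanopic contrast depends on the surrogate primaries; it is
  reproducible and maximal *for this rig*, not a reproduction of any
  measured rig's value (see the constraint analysis above).
- The observer and behaviour models are intentionally minimal; they
  exercise selection rules and analysis calibration, not human perception.
- CIELAB offsets-only policy: absolute published a\*b\* centres are not
  reproduced, and candidate luminance spread from per-candidate re-solves
  under unknown constraints is not emulated (candidates share the centre
  luminance).
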
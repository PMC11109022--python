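# Methods

## Data model

A recording is a set of equal-length expression tracks — per-frame
intensities in [0, 1] for the fixed channel tuple (neutral, happy, sad,
angry, surprise, fear, disgust, contempt) at a common frame rate (50 fps in
the intended use) — plus a seat map on an integer (row, seat) grid and
participant metadata (age, gender, empathy questionnaire total,
questionnaire-completion flag). Automated face-model fitting fails per face,
not per channel, so missingness is frame-atomic: if any channel is absent at
a frame, the whole frame is invalid and none of its values are used. Frames
are 0-based; frame *t* occurs at *t*/rate seconds.

Empathy totals are accepted on two scales (EQ-short 0–44, QCAE 4–124) and
are used only as totals; pair analyses sum them, so pairs should come from
audiences measured on one scale.

## Synchrony computation

Within a sliding window of `window_len` frames (default 3000 = 60 s)
advanced by `step` frames (default 100 = 2 s) until the last full window,
each channel of each participant is Pearson-correlated with the same channel
of every other participant over the jointly valid frames of that window. A
pair's window value is missing when joint coverage is below
`min_valid_fraction` (default 0.5 — an artifact choice; windows dominated by
occlusions would otherwise bias ISC toward 0) or when either series is
constant in the window. The ISC time course is the arithmetic mean of *raw*
r values over defined pairs per window and channel; Fisher's z = atanh(r) is
applied only where correlations enter inference, and r = ±1 is clipped at
1 − 1e−7 first so z stays finite (z ≈ 8.41 marks a numerically perfect
correlation).

Pair-level ISCs (the outcome of the proximity and pair-characteristic
analyses) are computed in two selectable modes, because the aggregation is a
genuine methodological fork: `whole_series` (default) correlates over all
jointly valid frames of the performance; `window_mean` averages per-window
Fisher-z values and back-transforms. The mode is logged with every output.

The implementation computes windowed moments with cumulative sums and
all-pair moments with masked matrix products; both paths are verified
against a naive loop-based Pearson implementation to 1e−10 in the tests.

## Inclusion

Participants are retained when their valid-frame fraction strictly exceeds
0.9 ("more than 90%", so exactly 90% is excluded) and, by default, when
their questionnaires are complete. If fewer than two participants survive,
the performance is excluded as a whole (an audience of one has no pairs).
The filter is idempotent.

## Engagement analysis

The scene script assigns a 1–3 score to contiguous whole-second scenes.
Scene intervals are half-open [start, end): a frame exactly at a boundary
belongs to the later scene, so scenes partition time without double
counting. The frame-level score series is averaged within the same sliding
windows as the ISC, which smooths transitions; the resampled course is a
contraction (it stays within the scene-score range and equals the score
wherever a window lies inside one scene).

Per channel, the ISC time course is correlated with the resampled course
over their shared non-missing windows (Pearson r, with a directional Bayes
factor). The regression stage fits all 2⁸ subsets of the eight channel ISCs
by least squares on listwise-complete windows and scores them with the BIC
posterior-odds proxy below. Overlapping windows induce strong
autocorrelation in both series; as in the field's practice for this design,
no autocorrelation correction is applied to r or the Bayes factors, and the
output flags this (`autocorrelation_corrected = False`). Perfect fits are
handled by flooring RSS at a tiny positive value for the BIC only; the
reported R² uses the true residuals.

## Proximity and pair characteristics

Seat distance is Euclidean in seat units (adjacent seats and adjacent rows
both 1 unit). The proximity covariate is √distance, which normalizes the
right-skewed distance distribution. The test statistic is the Pearson
correlation between √distance and pair Fisher-z ISC; inference is by
permutation: ISC values are shuffled across pairs (default 10,000 draws) and
the correlation recomputed.

The p-value rule "proportion of permuted correlations greater than or equal
to the observed" is direction-ambiguous when the observed correlation is
negative, so three conventions are exposed and logged: `directional`
(default; one-sided in the hypothesized direction, k/n), `paper_literal`
(upper-tail count regardless of direction) and `add_one` ((k+1)/(n+1)).
Under the null generator the directional rule is calibrated: the acceptance
run measures a rejection rate near 5% at α = 0.05.

Pair groupings: gender pairs are female (both female), male (both male) or
different; participants of other/unknown gender exclude the pair from gender
contrasts. Age pairs are young (both < 25), old (both > 25) or different —
the strict inequalities leave age exactly 25 unclassified, so any pair
containing a 25-year-old is "different". Pairs are only formed within a
performance; pooled analyses concatenate pair tables flatly (no hierarchy),
which the outputs flag. Total age and total empathy are pair sums; missing
components propagate as missing.

The gender/age contrast compares three nested linear models on pair z —
age-group main effect only (the null, since the age effect is tested
separately), + gender main effect, + gender×age interaction — using the BIC
proxy. Models made unidentifiable by empty cells are skipped with a warning,
never fabricated.

## Bayesian inference

*Paired t-test.* BF₁₀ = ∫ Cauchy(δ; 0, s) p(t | δ√n, ν) dδ / p(t | 0, ν)
with ν = n − 1, the standard default-prior (JZS) construction; default scale
s = 0.5, truncated to δ > 0 for directional hypotheses (prior renormalized,
i.e. doubled on the positive axis). The integrand is evaluated in units of
the null likelihood so the quadrature's relative error control survives
likelihood underflow at large |t|, and the integration range is split at the
likelihood peak. Integration failing 1e−6 relative tolerance raises rather
than returning silently. Posterior median and central 95% credible interval
come from the normalized integrand on a grid refined until the interval
endpoints move < 1e−3. The implementation agrees with dense-grid trapezoid
integration to ≪ 1% and with pingouin's independent JZS implementation to
1e−4 relative (tests).

*Correlation.* The sampling density of r given ρ (bivariate normal) is
integrated against a stretched symmetric beta prior on (−1, 1) with density
∝ (1 − ρ²)^(1/w − 1); the width w is taken equal to the configured Cauchy
scale, matching the kappa convention of standard Bayesian-statistics
software (w = 1 is the uniform prior, confirmed against pingouin; the
default w = 0.5 gives Beta(2, 2)). One-sided tests truncate to ρ > 0.

*Model comparison.* Regression and ANOVA-style comparisons use
BIC = n ln(RSS/n) + k ln n and score ∝ exp(−BIC/2) normalized over the model
set under a uniform model prior. This is an approximation to full Bayesian
regression model odds — orderings and orders of magnitude are the contract,
not exact parity with any particular software's BF values — and every output
row is tagged with its method (`jzs-ttest`, `jzs-correlation`,
`bic-approx`).

## Synthetic audience generator

The generator is the package's ground-truth instrument; each analysis
hypothesis corresponds to one knob.

1. **Engagement gating.** The script gives e(t) ∈ {1, 2, 3} per frame; the
   coupling gain is g(t) = (e(t)/3)^γ (γ = 0: no gating; default γ = 1).
2. **Shared signal.** Per channel, s_c(t) is a standardized moving average
   (length L = 50 frames = 1 s by default) of unit-normal noise.
3. **Spatial field.** Per channel, at each of ⌈T/L⌉ time blocks a
   participant vector is drawn from N(0, Σ), Σᵢⱼ = exp(−dᵢⱼ/λ) (Euclidean
   seat distance; λ = 3 seats by default), realized through a symmetric
   eigenvalue root with 1e−9 diagonal jitter, upsampled by repetition and
   standardized per participant.
4. **Trait coupling.** wᵢ = logistic(β_age z(ageᵢ) + β_emp z(empᵢ) +
   β_gender 1[femaleᵢ]) with within-audience standardization; β = 0 by
   default. Ages are uniform on 18–80, empathy is normal at the scale
   midpoint (SD one sixth of the range, truncated to the scale), gender is
   Bernoulli(½).
5. **Observation.** x_ic(t) = clip(μ_c + κ_c g(t) wᵢ (s_c + u_ic) a +
   σ ε, 0, 1) with fixed amplitude a = 0.1, κ_c = 1, σ = 0.05. Clipping
   (rather than a logistic squash) matches the bounded classifier output.
   Channel baselines μ_c default to magnitudes typical of theatre audiences:
   0.68, 0.10, 0.08, 0.08, 0.01, 0.02, 0.02, 0.065.
6. **Dropout.** ⌈δT⌉ frames per participant (δ = 0.02 by default) are
   invalidated as up to three non-overlapping contiguous runs at random
   positions, emulating face-model failure episodes; the invalid count is
   exact.

All randomness descends from one seed through child generators spawned in a
fixed order (traits; shared signals; spatial fields; per-participant noise;
per-participant dropout), so output is a pure function of (config, seed) and
enlarging the audience does not perturb the shared components.

**What the generator does not emulate:** realistic facial dynamics, actor
events, lagged mimicry (only zero-lag synchrony), non-stationary baselines,
classifier calibration drift, or correlated dropout across neighbours.
Passing recovery tests therefore show that the pipeline recovers the stated
effects under this model's assumptions, not that real audiences satisfy
them.

## Verification study conditions

The acceptance checks (tests and `scripts/acceptance.py`) run at sizes
chosen to finish in minutes on one CPU while leaving clear statistical
margins:

- *Oracle equivalence:* 50 random recordings (2–6 members, 150–600 frames,
  up to 30% dropout), every windowed pair r vs a naive implementation,
  tolerance 1e−10.
- *Permutation calibration:* 500 null audiences (n = 20 on a 4×5 grid,
  1000 frames), 1000 permutations each; rejection rate at α = 0.05 expected
  in 3–7%.
- *Proximity recovery:* 100 audiences (n = 40 on a 5×10 grid, 6000 frames,
  λ = 3); negative proximity correlation with p < 0.05 expected in ≥ 90.
- *Engagement recovery:* 600 s recordings with an 18–30-scene script,
  n = 6, κ = 0.3, analysed with non-overlapping 2 s windows — chosen so the
  window series are effectively independent and the ISC estimate is
  noise-limited; under those conditions mean best-model R² increases
  strictly over γ ∈ {0, 1, 2} (30 seeds each) and the happy-ISC/engagement
  correlation is positive at γ = 2. With the default 97%-overlapping 60 s
  windows the R² comparison is dominated by autocorrelated spurious fits
  and by the convexity of the ISC-vs-gain mapping, which is why the
  recovery check uses independent windows.
- *Within-expression structure:* one audience (n = 40, 3000 frames,
  constant gain); every individual's mean on-diagonal Fisher-z exceeds the
  off-diagonal mean, paired-t BF₁₀ > 10.
- *Trait recovery:* 30 audiences (n = 40, 3000 frames, β_emp = +1.5,
  β_age = −1.5); the two correlation signs recovered in ≥ 90%.
- *Bayes oracle battery:* t ∈ {0, 1, 2, 3} × n ∈ {20, 50} and
  r ∈ {0, 0.3, 0.9} × n ∈ {10, 50}, both sidednesses, ≤ 1% relative error
  vs dense-grid integration.

## Numerical choices and degenerate inputs

- Correlations are undefined (missing, never 0) for < 3 joint frames, for
  series constant up to float rounding (tolerance 1e−12 relative), and for
  windows below the coverage threshold; undefined entries are excluded from
  averages.
- Fisher clipping ε = 1e−7; round-trip error ≤ 1e−12 for |r| ≤ 0.999.
- The λ → ∞ limit of the spatial field is exact only up to the covariance
  root's conditioning jitter (~1e−4 in track values).
- Whole-performance exclusion exits the CLI with a documented code (3);
  empty model cells and constant covariates produce warnings, not values.

## Known limitations

- The BIC proxy understates model uncertainty relative to full Bayesian
  regression averaging; use it for ranking, not for evidence magnitudes.
- Overlapping windows make engagement correlations anti-conservative; the
  package reports this flag but deliberately applies no correction.
- Pooling pairs across performances is flat; audiences of very different
  sizes will weight the pooled analyses unevenly.
- The permutation test treats pairs as exchangeable although pairs sharing
  a member are weakly dependent; calibration holds under the null generator
  (measured), but strong participant-level heterogeneity could perturb it.
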
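# audiencesync

Inter-subject correlation (ISC) analysis of audience facial expressions.

When many people watch the same live performance, their facial expressions
tend to rise and fall together. `audiencesync` quantifies that synchrony from
automated facial-expression classifier output — per-frame intensities in
[0, 1] for eight channels (neutral, happy, sad, angry, surprise, fear,
disgust, contempt) at 50 frames/s — and relates it to properties of the
performance and of the audience. It is written for researchers studying
collective emotion, engagement measurement and emotional contagion in
audiences.

## The method

**Synchrony.** For every pair of audience members *(i, j)* and every
expression channel *c*, the Pearson correlation
r<sub>ij</sub><sup>c</sup> is computed within a sliding window (default 60 s
= 3000 frames, advanced in 2 s = 100-frame steps). Averaging the pairwise r
values per window and channel gives the audience's ISC time course; whole-
performance pair correlations give a pair-level ISC table. Correlations are
variance-stabilized with Fisher's transform, z = atanh r, before any
inference. Frames where the face model failed are missing as a whole;
correlations use pairwise-complete frames and a window is reported missing
below 50% joint coverage.

**Inclusion.** Only participants whose face could be modelled for strictly
more than 90% of the performance and who completed all questionnaires enter
the analyses; a performance with fewer than two eligible members is excluded.

**Engagement.** A scene-by-scene 1–3 engagement script (whole-second
boundaries) is expanded to the frame grid and resampled with the same
sliding window, then each channel's ISC time course is correlated with it
(directional Bayes factor under a Cauchy(0.5) prior truncated to positive
effects) and all 2⁸ subsets of the eight ISC predictors are compared with
BIC-approximated posterior odds.

**Proximity.** Seats sit on an integer grid (adjacent seats and adjacent
rows are 1 unit apart). Pair ISC (z) is correlated with √(Euclidean seat
distance), and the correlation is tested against a permutation null obtained
by shuffling ISC values across pairs (10,000 draws by default).

**Pair characteristics.** Per pair: total age, total empathy (EQ-short or
QCAE totals), gender group (female/female, male/male, different) and age
group (young: both < 25; old: both > 25; different otherwise) — analysed
with Bayesian correlations and BIC model comparisons.

**Bayesian layer.** JZS Bayes factors for paired t-tests (Cauchy effect-size
prior, numerical integration, validated against brute-force integration and
an independent implementation) and for Pearson correlations (stretched
symmetric beta prior on ρ); BIC posterior-odds proxies for regression/ANOVA
model comparison.

A synthetic-audience generator (`audiencesync.synthetic`) produces
recordings with known ground truth — an engagement-gated shared signal, a
spatially decaying coupling field over the seat grid, trait-modulated
coupling weights, and frame dropout — so every stage of the pipeline has a
parameter-recovery test.

## Worked example

Simulate an 8-member audience over a 10-minute performance whose generator
couples expression synchrony to an 18-scene engagement script
(`engagement_exponent: 2.0`), decays coupling with seat distance
(`spatial_length: 3.0`) and modulates it by traits (`beta_age: -1.0`,
`beta_empathy: 1.0`):

```bash
audiencesync simulate --config sim.yaml --out-dir demo/sim
audiencesync analyze \
    --expressions demo/sim/expressions.csv \
    --metadata demo/sim/metadata.csv \
    --script demo/sim/script.csv \
    --window-len 1000 --step 500 --n-perm 2000 --seed 11 \
    --out-dir demo/out
audiencesync report --out-dir demo/out
```

The report (abridged) reads:

```
## Within- vs between-expression synchrony
- mean on-diagonal z = 0.109, off-diagonal z = -0.001 (8 individuals)
- Bayesian paired t-test (method jzs-ttest): BF10 = 31.7, posterior median 1.263, 95% CI [0.271, 2.442]

## Engagement (method jzs-correlation / bic-approx)
- neutral: r = 0.837, BF10 = 3.95e+13
- happy: r = 0.795, BF10 = 1.77e+11
- best regression model: happy+surprise+disgust (R^2 = 0.869, posterior score 0.078)

## Proximity (permutation test)
- happy: r = -0.338, p = 0.0355 (2000 permutations, rule directional)

## Pair characteristics (method jzs-correlation)
- happy ~ total_age: r = -0.763, BF10 = 6.34e+03
- happy ~ total_empathy: r = 0.788, BF10 = 1.91e+04
```

Reading the numbers: individuals synchronize *within* expression (each
person's happy trace correlates with the rest of the audience's happy trace,
mean Fisher-z 0.109) but not across expressions (−0.001), and the Bayes
factor of 31.7 is strong evidence for that contrast. Expression ISCs track
the scripted engagement (r ≈ 0.8, decisive Bayes factors, best predictor
subset explaining 87% of engagement variance). Synchrony falls with seat
distance (negative r against √distance, permutation p < 0.05 for most
channels) and is higher for younger, more empathic pairs — each the sign the
generator planted.

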
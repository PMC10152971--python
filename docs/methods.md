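# Methods

This note documents the models, estimators and numerical choices behind the
package, the conditions its synthetic data encode, and what the test suite
does and does not demonstrate.

## Stimulus calibration

For the 750 Hz, 4 ms tone burst (one cycle rise/plateau/fall, 4 per second)
all level scales are affine in the device dial level (dB HL):

| mode | transducer | dB nHL | physical scale |
|------|------------|--------|----------------|
| BC   | B71 mastoid vibrator | HL − 14 | dB FL = HL + 49 |
| AC   | TDH39 headphones     | HL − 12 | dB SPL = HL + 9 |

The offsets are stored as named constants (they come from the transducers'
RETSPL calibration for this stimulus); re-deriving them from the underlying
acoustic-calibration standards is out of scope.  Conversions accept any
float; only the staircase enforces the 5-dB grid.  The staircase starts at
100 dB HL (86/88 dB nHL for BC/AC — the protocol's reference level), steps
by 5 dB, and can ascend to the 110 dB HL device ceiling when the start gives
no response.  The device floor for the descent is not documented anywhere we
could find; the package uses 60 dB HL, safely below every plausible pediatric
threshold, and exposes it in `StaircaseProtocol`.

## Synthetic cohorts

`sample_cohort` draws a cohort whose latent structure matches what the
analysis assumes.  Defaults encode the study conditions: 118 children aged
0.5–16 years plus 41 adults aged 16–62, balanced sexes, both ears tested in
AC and BC.

**Amplitude ratio.**  The per-ear ratio is
`m_mode(age, sex) · exp(η)` with the maturation curve

```
m(age) = s_sex · [b + g·(age/t)·e^(1 − age/t) − d·max(0, age − t)]
```

which peaks exactly at `t` years.  Defaults (AC: b=0.75, g=1.3, t=5,
d=0.008; BC: b=1.3, g=0.8, t=4.5, d=0.02; male multiplier 1.15/1.10) were
matched once to the child and adult band means of the measured
characteristics table and then frozen; the decline rates keep the curve
positive through age 62, which flattens the adult decline relative to the
child data — the reference fit only uses the 0.5–16 year domain, so this
does not affect the normative estimates.  The log-scale noise
`η = √c·τ·u + √(ρ−c)·τ·v_mode + √(1−ρ)·τ·w_ear` has total SD `τ = 0.4`
(matching the ~0.3–0.5 coefficients of variation of the printed per-band
ratios), right–left correlation `ρ = 0.85` (the printed ICC) and AC–BC
correlation `c = 0.6` (the printed cross-mode r).  Log-normal rather than
additive effects keep ratios positive and give the Box-Cox step a genuine
skewness to undo.

**Thresholds.**  `θ0 − 4·ratio + N(0, 3²)` dB nHL (θ0 = 83 AC / 81 BC),
snapped to the staircase ladder; values above the ceiling become absent
responses.  These intercepts put typical child thresholds near 76 (AC) and
74 (BC) dB nHL, the values of the per-band reference table; summary
thresholds quoted elsewhere in dB nHL around 86–88 are consistent with these
once read as dB HL dial values.  BC responses are additionally absent with
probability 0.05 from age 14 and 0.15 in adults, reproducing the loss of BC
responses from mid-adolescence.

**Latencies.**  Bump centres `c_P = 12.8 + 0.05·age + N(0, 0.4²)` ms and
`c_N = c_P + max(N(6.3, 0.8²), 3)` ms.  The stored *true* latencies are the
peak times of the noiseless biphasic waveform (Newton refinement of the
two-bump shape), not the bump centres: the opposite-polarity bump shifts
each peak by up to ~0.3 ms at small P–N gaps, and a latency measurement
estimates the waveform peak.

**Waveforms.**  Each epoch is stationary Gaussian noise with a flat 20–450 Hz
band spectrum (synthesised in the frequency domain — no filter edge
transients — with RMS equal to the subject's tonic EMG level, drawn
uniformly from the 100–500 µV biofeedback target band) plus the biphasic
response `A·[exp(−(t−c_P)²/2w²) − exp(−(t−c_N)²/2w²)]`, `w = 2` ms.  `A` is
scaled so the noiseless peak-to-peak equals `ratio · EMG · growth(level)`,
where growth rises linearly in dB from 0 at threshold − 5 to 1 at the
reference level (clamped to [0, 1]); clinical protocols do not state a
growth function, so the linear 15-dB-span ramp is a package choice.
Averages use 25 epochs for children at the reference level and 50 during
threshold search (the protocol raises acquisitions to 50 when a decision is
unclear, which is also why the reference level carries two extra 50-epoch
validation averages); adults use 50 throughout.  Sessions descend to two
steps below the true threshold and carry four validation averages per
search level.  All randomness flows from one seed through per-subject
streams.

What the generator does **not** model: real EMG spectra and
non-stationarity, the two testing positions and their EMG offset, artifact
contamination, and adult longitudinal decline.  Passing tests therefore
demonstrate correctness of the algorithms under the stated statistical
structure, not clinical performance on recorded data.

## Feature extraction

* **EMG level**: rectified mean over 50–150 ms, i.e. excluding the response
  window.  Whether the published protocol used a pre-stimulus,
  whole-window or response-excluded segment is not stated; the window is a
  config knob (`emg_window_ms`).  For a Gaussian background the rectified
  mean is `RMS·√(2/π)`; measured amplitude ratios are therefore a fixed
  ≈1.25 factor above the generator's RMS-normalised latent ratios, which is
  immaterial because the normative model is built on the same measured
  scale.  Simulated averages carry the per-epoch EMG as metadata, matching
  the normalisation "from individual traces".
* **Peaks**: P is the maximum of a zero-phase 200 Hz low-passed copy in
  8–18 ms, N the minimum in [P + 2, 30] ms, each snapped to the raw local
  extremum within ±0.4 ms (the smoothing removes the low-frequency EMG
  rumble that would otherwise dominate a raw argmax; the snap removes the
  filter-induced shift).  Amplitudes are read from the raw samples at the
  detected latencies, so the noiseless round trip is exact.  Search windows
  bracket the observed latency ranges (P 10.8–15.8, N 14.6–24.8 ms) with
  margin.  Response presence requires the peak-to-peak amplitude to exceed
  `k = 3` times the robust (MAD-based) noise scale of the post-response
  segment.
* **Replicability**: two successive averages are replicable when both show a
  present response, their P latencies agree within 2 ms, and their Pearson
  correlation is at least `r_min = 0.45`, computed on the 5–35 ms window
  after a 40–200 Hz zero-phase band-pass.  Rationale: the P–N complex (two
  opposite 2-ms Gaussian flanks ~6 ms apart) is spectrally an ~80 Hz
  wavelet, while the 20–40 Hz part of the EMG background contributes only a
  handful of effective degrees of freedom per 50-ms window and would
  otherwise dominate the correlation; the threshold was set from a noise-only
  false-positive budget (<1% per comparison, measured ~0.5%), not from the
  sensitivity side.  All of `r_min`, `k`, windows and bands are config
  knobs.
* **Threshold**: descending walk from the reference level while replicable;
  the threshold is the lowest replicable level.  When a level carries more
  than two validation averages the walk retries with the next adjacent
  replicate pair before declaring failure (an examiner keeps acquiring until
  reproducibility is decided).  If the start is not replicable the walk
  ascends to the ceiling; never replicable ⇒ response absent.  Under the
  default SNR this lands within 5 dB of the generator's truth for ≈99% of
  200 simulated ears, with absent ears flagged correctly.

## Reference-interval estimation

The Royston–Wright fit, per conduction mode with sex strata:

1. **Transform.** `B = ((y + shift)^λ − 1)/λ`, log at λ = 0.  The
   three-parameter modulus-exponential-normal family is deliberately reduced
   to Box-Cox-normal: skewness is handled by λ and no separate kurtosis
   parameter is fitted; the published centile tables are reproducible from
   this sub-family, which is also the only step the published method
   description enumerates.
2. **λ profile.** λ is profiled on the grid [−2, 2] step 0.05, with the
   Gaussian log likelihood including the Jacobian `(λ−1)Σ log y`.  During
   profiling the mean uses the best-fitting fractional polynomial of degree
   ≤ 2 (lowest RSS pooled across strata) and a constant ML σ per stratum —
   this keeps the profile smooth in λ; letting the significance-tested
   selection run inside the profile makes it jagged and inflates the λ
   variance.  λ is shared across sexes within a mode (a stability choice at
   these stratum sizes; the published account does not state the λ scope).
3. **Curves.** At λ*, the μ power set (degree ≤ 2, powers from
   {−2, −1, −0.5, 0, 0.5, 1, 2, 3}, power 0 = log) is selected by the
   closed deviance test at α = 0.05 — degree 2 vs null, vs linear, vs best
   degree 1 — on the RSS pooled across sexes; coefficients are per sex.
   Sharing the power set (not the coefficients) across strata parallels the
   shared λ and removes most of the selection variance at n ≈ 118 per
   stratum.  σ(age) comes from regressing `√(π/2)·|residual|` on a
   fractional polynomial of degree ≤ 1 (Gaussian folded-mean identity),
   selected the same way, then scaled by `√(n/(n − p_μ))` to return the
   variance absorbed by the mean fit.  A σ curve that goes non-positive
   anywhere on the age domain falls back to a constant SD with a warning;
   evaluation floors σ at 10⁻³.
4. **Diagnostics.** Z-scores per stratum with Shapiro–Wilk p, corr(Z, age)
   and corr(|Z|, age); `gof_ok()` requires p > 0.05 and |corr(Z, age)| < 0.1.
5. **Centiles.** `invBoxCox(μ(age) + z_p σ(age))`; an inverse argument
   outside the transform's range is clamped at zero with a warning.  The
   normative table reports the 5th/10th centile, back-transformed μ
   ("mean"), and the 90th/95th centile for integer ages 1–15 per sex.

Records below 0.5 years are excluded before fitting (mirroring the exclusion
of the youngest participant); ears enter as independent observations, as in
the source analysis, which pooled ears after confirming right–left agreement.

**Recovery performance** (measured by `tests/test_acceptance.py` at the
documented scale of 100 cohorts × 236 ears, seeds 1–100, both modes): the
fitted λ has median |error| ≈ 0.10 against the log-normal truth (per-cohort
SD ≈ 0.17, which is the intrinsic Box-Cox ML variability at n = 236); the
95th-centile curve over ages 1–15 has a pooled median absolute relative
error ≈ 8% (per-fit RMS ≈ 11–12%, dominated by the age-1 and age-15 curve
ends where the data carry the least information); the empirical 5–95
coverage of the training data is ≈ 0.90.

## Cohort statistics

* Asymmetry `100·(R − L)/(R + L)`; empirical limits are the
  (coverage/2, 100 − coverage/2) percentiles with the type-7
  linear-interpolation rule (recorded in the output metadata; the source
  does not name its rule).  The classification cut defaults to 35% (the
  published normality criterion) with 32% — the rounded empirical band —
  available by configuration.
* ICC defaults to the one-way random-effects, single-measurement form
  ICC(1,1) with the exact F-based confidence interval, implemented directly
  from the ANOVA mean squares; the test suite cross-checks it against an
  independent implementation.  The published 0.84/0.86 values are
  descriptive, not recovery targets.
* Group comparisons (Wilcoxon–Mann–Whitney, Welch, paired t) are thin
  pass-throughs to scipy and carry no methodological weight here.

## Determinism and problem sizes

Every stochastic stage takes a seed; `run-all` writes a manifest with the
resolved configuration and SHA-256 of each artifact, and repeated runs with
one seed are byte-identical.  The test suite uses scaled problem sizes
chosen to keep statistical assertions sharp: 100 cohorts × 236 ears for
reference-model recovery, 200 ears for staircase accuracy, 2000 pairs for
ICC/asymmetry recovery (evaluated in a narrow age band so the agreement
target is not inflated by the shared age trend), and a 48-child + 12-adult
cohort for the byte-identity run of the full pipeline.

## Known limitations

* The Box-Cox-normal family cannot represent residual kurtosis; the full
  modulus-exponential-normal family is an extension hook, not implemented.
* Ears are treated as independent in the fit; a cluster-robust treatment of
  the subject effect is not implemented, so standard errors of the curves
  (not reported) would be optimistic.  The centile point estimates are
  unaffected.
* The replicability criterion quantifies a judgement the original protocol
  made visually; its operating characteristics are tuned to the synthetic
  noise model and would need re-calibration for recorded data.
* Adult ages enter the generator and descriptive statistics but not the
  reference fit, whose domain ends at 16 years.
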
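# Methods

## The record and its model

A baleen plate is read as a uniformly sampled spatial time series: position
x (cm) from the most recently grown end, testosterone T(x) in ng of
immunoreactive hormone per g of baleen powder, optionally δ¹⁵N(x) in ‰ on
the same grid. Larger x is older growth. The working model of an adult
male's record is an annual pulse train: a narrow T elevation once per cycle
over a low baseline, with the local cycle length (14–22 cm here) set by the
baleen growth rate, which slows as the whale ages; the isotope series is a
sinusoid of the same local period whose crest the T pulse leads by a few
months (mating precedes peak summer foraging). Deviations the model admits:
an acyclic juvenile prefix at the old end of a young whale's plate (cycling
had not yet begun), and senescent drift (pulse amplitude declining while the
baseline rises over the oldest whales' later years).

## Pipeline stages and the choices behind them

**Detrending.** The AR spectrum must not be dominated by slow drift
(multi-year trends in deposition or extraction efficiency), so each series
is detrended by subtracting a Gaussian low-pass smooth. The filter width is
not dictated by the problem; the default σ = 8 cm is a compromise fixed by
the transfer function H(P) = exp(−2π²σ²/P²) (fraction of a P-cm sinusoid
passed into the trend): the annual band largely survives in the residual
(99.3% of amplitude at 16 cm, 92.6% at 22 cm) while slow variation is
substantially absorbed (≥ 70% at 60 cm and beyond). A wider filter would
preserve 22-cm cycles better but let 60–120 cm drift through. σ is
configurable and recorded in every report. Boundaries are handled by
reflection (no spurious edge trend on a finite plate); the kernel is cut at
±4σ. Property tests assert the measured attenuation against H(P) itself.

**Period estimation.** Yule–Walker AR fits via the Levinson–Durbin
recursion on the biased sample autocovariances; order chosen by
AIC(p) = n·ln σ̂²ₚ + 2p over p = 0…max_order (constants in the likelihood
cancel in the argmin; ties go to the smaller order). max_order defaults to
min(⌊n/3⌋, 40): high enough to resolve a multi-harmonic pulse train on a
90–165-sample plate, bounded to prevent overfit. The spectral density of
the selected model is evaluated on a 4096-point frequency grid and the
period read from the highest in-band local maximum (ties toward lower
frequency); period = spacing / f_peak. The search band (default periods
4–60 cm) excludes sub-seasonal noise and residual trend; a spectrum with no
in-band local maximum raises a "no dominant cycle" error rather than
returning an argmax at a band edge.

Accuracy note: on noiseless synthetic pulse trains the AIC-selected
all-pole fit places the peak ~0.03–0.05 cm from the true 16-cm period (an
AR(9) approximation to a line spectrum with 4 harmonics); R's `spec.ar`
reproduces the same value on the same series. Fixed orders ≥ 16 would be
exact to the grid, but order selection is part of the method. At 10% pulse
noise the estimate stays within 0.5 cm of truth in ≥ 95% of replicates
(measured: 100/100).

**Phase.** CCF(k) = corr(T_{i+k}, N_i), biased-covariance estimator with
full-series normalization (|ccf| ≤ 1 guaranteed). Since larger x is earlier
time, a positive best lag means T precedes the isotope signal. The search
is limited to half the isotope period so the match cannot lock onto the
neighbouring cycle, and the offset is converted to months with the **T**
period (offset = |k|·spacing/period × 12): this is the unique convention
consistent with every printed offset in the reference table (e.g.
2/14.49 × 12 = 1.66). Offsets are therefore quantized to one sample
(1.1–1.7 months here); a best correlation below 1.96/√n is flagged
non-significant but still reported.

**Peaks, cycles, ages.** The peak rule is deliberately minimal: a sample
strictly greater than its two prior and two subsequent neighbours. Strictness
means tied plateaus yield no peak, and the first/last two samples never
qualify. On noisy series the strict rule fires on noise bumps in the flat
baseline troughs, so an optional minimum-prominence filter is provided
(default off = the pure rule); the pipeline expresses the threshold in
units of a robust noise scale estimated from the 25th percentile of
absolute first differences (the median would be contaminated by pulse-edge
differences when a cycle spans only 7–11 samples). Cycle minima take the
smallest strictly-interior value, ties resolved toward the midpoint then
earlier — any deterministic rule would do; this one is symmetric. The
per-cycle peak/minimum ratio divides each cycle's leading peak by its own
minimum (the mean-peak-over-baseline variant is available via the summary
fields); %CV of peaks uses the n−1 SD. Per-cycle (and per-peak) ages
follow the terminal-age convention: with n cycles and estimated age at
death A, the oldest documented cycle occurred at age A − n and the most
recent at A − 1.

**Age estimation.** Precedence: explicit override (sensitivity runs) >
AAR eye-lens age > length-derived. Length inversion is by bisection on the
monotone forward von Bertalanffy curve (bracket 0–250 yr, tolerance
0.01 yr); a length at or beyond the asymptote raises an error, which the
length-only mode uses to fall through two-stage → single-stage →
length-class comparator average. Growth parameters are configuration, not
constants: the shipped `growth_params_synthetic.yaml` is a synthetic
calibration fixture fitted so the forward curves reproduce a published set
of male bowhead (length, age) pairs within rounding; production use should
substitute the published parameter values.

**Age-trend inference.** Candidates: response ~ 1 + (1|whale),
response ~ age + (1|whale), response ~ age + (1+age|whale) with
unstructured 2×2 random-effect covariance; Gaussian likelihood via
statsmodels MixedLM. Model ranking uses ML and AICc =
−2ℓ + 2k + 2k(k+1)/(n−k−1) with k counting fixed effects + all
variance/covariance parameters + the residual variance (k = 3/4/6), the
convention that reproduces the reference table's AICc values from its
log-likelihoods; the winner is refit by REML for reported estimates.
Fixed-effect t statistics use the nested-grouping denominator
df = N − G − q (q = fixed covariates varying within whales), giving
126 − 9 − 1 = 116 at the study shape. Numerical choices: the age covariate
is standardized internally (ages span 7–152 yr; the raw parametrization
leaves the optimizer prone to spurious optima) and everything is
back-transformed, with the REML log-likelihood corrected by −log(sd) to the
natural parametrization; fits whose fixed-effect covariance is singular
(NaN SEs) are treated as non-converged and retried with other optimizers;
a random-effect variance estimated at numerically zero sets a boundary
flag rather than failing. The implementation is cross-validated against R
nlme's `lme()` on a frozen dataset (ML and REML log-likelihood and fixed
effects agree to ~10⁻⁵). Visual residual inspection is replaced by a
reported Shapiro–Wilk statistic and a scale-location slope — descriptive,
not gatekeeping. Pearson tests of plate summaries vs terminal age are
two-tailed at α = 0.05 on n − 2 df.

**Pipeline.** Per whale: optional analysis window (e.g. restricting a
juvenile's plate to its cycling half — configuration, not changepoint
detection) → detrend → ACF diagnostic → AR period (T and δ¹⁵N) → peaks →
cycles/summaries → phase → ages; cohort: mixed models for peak T ~ age and
period ~ age, correlations under the configured age mode. Per-whale
failures are recorded and skipped; cohort stages run on the survivors.
Reports carry no timestamps and iterate whales in sorted order, so a rerun
with the same inputs is byte-identical.

## The synthetic generator

T(x) = baseline_c + amplitude_c·g(φ(x)) + ε, where c indexes cycles from
the oldest end, g is a unit-height circular Gaussian pulse whose FWHM is
`peak_width_fraction` (default 0.2) of a cycle, and the phase φ advances
2π per local period, the period shrinking by `period_decline_cm_per_cycle`
toward the recent end. δ¹⁵N(x) = mean + amplitude·cos(φ − 2π·lead/12)
continues through any juvenile acyclic prefix (isotope cycling does not
depend on maturity). Noise is additive Gaussian, clipped at zero (clip
events counted in the truth record). The piecewise-per-cycle period (not a
continuous drift) keeps truth bookkeeping exact: every pulse centre,
per-cycle period, baseline, amplitude and back-calculated age is recorded.

Defaults for the nine-whale scenario are shaped on the published cohort:
plates 181–330 cm, terminal ages 14–153 yr, mean periods ≈ 14.5–21.5 cm
with the per-cycle decline fixed at 0.045 cm/cycle (the published
period-versus-age slope, one cycle = one year), a 3-month-scale phase lead
(zero for the juvenile whale, whose cycles are synchronous), an 85-cm
juvenile prefix on the youngest whale, and senescent trends
(−0.18/−0.22 ng/g per cycle amplitude with +0.03/+0.05 baseline) on the two
oldest. T noise defaults to 5% of the pulse amplitude: large enough to
exercise noise-robust counting, small enough that every annual pulse —
including the diminished senescent ones — stands clear of the noise floor,
as on the real plates where every annual peak was countable. (At 10% white
noise the late senescent pulses are statistically inseparable from noise
bumps under any local peak rule; 10% is retained where it is the stated
condition of the spectral-recovery experiments.)

What the generator does **not** emulate: assay error structure and
extraction-efficiency gradients, sub-annual endocrine events, skipped or
"short" cycles, correlated (smoothed) deposition noise, and calendar
anchoring of cycles to months. Passing recovery tests therefore show the
pipeline recovers the assumed signal structure under white noise — not
that real plates satisfy those assumptions.

## Known limitations

- The detrending width of the original analysis is unreported; periods are
  therefore reproducible only up to the filter choice (σ = 8 cm default).
- Period estimates carry no uncertainty intervals, and lags are not
  interpolated below one sample.
- The denominator-df and AICc-k conventions are inherited software
  conventions, applied uniformly; other software (e.g. Kenward–Roger df)
  would print different t/p values.
- With 9 groups, 2-SE coverage of the fixed slope is theoretically ~92%,
  so recovery experiments at that shape sit near their nominal threshold.
- The growth-parameter file is a calibration fixture, not the published
  parameter set.

## Problem sizes used in tests

Recovery experiments use 100 seeded replicates each (AR period at 10%
noise; REML slope recovery and model selection at the 9-whale / 126-peak
study shape); the peak-rule oracle uses 200 random series; the end-to-end
round trip analyzes the full nine-whale scenario once at master seed 7.
These sizes give stable pass/fail behaviour at the stated thresholds while
keeping the default suite around a minute.
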
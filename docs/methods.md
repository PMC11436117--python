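# Methods

This note documents the models, numerical choices and design decisions
behind `specmdd`, and what the synthetic-cohort tests do and do not show
about real data.

## Spectral estimation

Per channel, the power spectral density is estimated by Welch's method with
a Hanning window, 2-s segments and 50% overlap; segments are mean-removed
before windowing (avoids DC leakage into delta), and the one-sided density
uses the standard window-power normalization `2 / (fs · Σw²)`. Segment
periodograms are combined by the **bin-wise median**, deliberately without
the asymptotic median-of-chi-square bias correction (≈ 1/ln 2): the
estimator is the plain median, matching its robust-estimation usage. Two
consequences worth knowing:

* for Gaussian noise the median estimator sits ≈ ln 2 below the mean-level
  density (the tests assert exactly this, and assert the mean-combined
  variant at the unbiased level);
* robustness is against *transient* artifacts: corrupting one 2-s stretch
  by a factor 100 changes the median spectrum's band-integrated power by
  < 10%, while the mean spectrum inflates by orders of magnitude. Single
  bins can still move by tens of percent, because removing 3 of 59 order
  statistics shifts the sample median by one to two order statistics —
  a granularity limit of the median at this segment count, not a bug.

The 0 Hz bin is retained in the spectrum object but excluded from all
fitting (the fixed-mode log model is undefined there). Frequency resolution
is 1/seg_seconds = 0.5 Hz by default.

## Spectral parameterization

The log10 spectrum over the fit range (default 1–45 Hz, the union of the
delta–gamma bands) is modeled as an aperiodic Lorentzian
`L(F) = b − log10(k + F^χ)` plus Gaussian peaks
`G(F) = a·exp(−(F−C)²/(2w²))`. In the default fixed mode `k = 0` and `L` is
a line in log-log space whose slope is −χ. The staged fit:

1. **Robust aperiodic fit** — an ordinary least-squares fit of `L` (closed
   form in fixed mode), then a re-fit restricted to bins whose positive
   residual is at or below its 2.5th percentile, which removes oscillatory
   regions from the background estimate.
2. **Iterative peak extraction** on the flattened spectrum: take the
   maximum; stop when it falls below `rel_threshold` (default 2.0) flat-SDs
   or the absolute floor `min_height` (default 0.10 log10 units); estimate
   the width from the half-height extent; subtract; repeat up to
   `max_n_peaks` (default 6). Two guards keep noise out: a residual maximum
   whose neighbors hold less than half its height is skipped (a feature
   narrower than ~2 bins is unresolvable at 0.5 Hz resolution), and of two
   guesses closer than 1.5× the wider SD only the stronger survives (one
   noisy peak must not split into two).
3. **Joint Gaussian refinement** of all peaks on the flattened spectrum,
   centers bounded within ±2 SD of their guesses (prevents drift onto
   neighboring structure), widths bounded by `width_limits` (default
   0.5–12 Hz FWHM).
4. **Aperiodic re-fit** on the peak-subtracted spectrum.
5. **Final joint refinement** of aperiodic and peak parameters together,
   with analytic Jacobians; `r²` and mean absolute error are reported in
   log10 space, and a convergence flag is set if any least-squares stage
   hit its iteration cap.

Measured behavior: noiseless model spectra are recovered to ≲ 1e-9 in every
parameter; with log-noise SD 0.05 the median exponent error is ≈ 0.01 and
the median peak-center error ≈ 0.07 Hz over 100 seeds (~6 ms per fit).
Threshold-level noise bumps (height ≈ 2 noise-SD) are occasionally fitted
as small peaks; they are the honest cost of the 2-SD threshold.

**Band features.** Bands are half-open `[low, high)` so shared edges are
unambiguous (8 Hz belongs to alpha). A peak belongs to the band containing
its center. The periodic band feature defaults to the mean modeled periodic
log-power over band bins, 0 when no peak is centered in the band; the
alternative statistic (largest in-band peak power `a`) is available via
`periodic_statistic="max_peak"` since the band statistic used for group
comparison is genuinely underdetermined — both are exposed, the default is
declared, the intent is not guessed. The same applies to the aperiodic
comparison feature: the exponent χ is the default, the offset `b` is
reported alongside.

## Synthetic cohorts

`synth.make_cohort` emulates the study conditions: 74 controls vs 40
depressed subjects, the 60 region-mapped 10-20 electrodes, 500 Hz, 60 s of
resting EEG each (60 s gives 59 Welch segments — enough for a stable
median — while keeping a full cohort tractable on one CPU; real recordings
may be longer, which only helps).

* **Aperiodic background**: inverse-FFT amplitude shaping of white Gaussian
  noise, amplitude ∝ f^(−χ/2), scaled so the one-sided PSD is
  `10^b · f^(−χ)` exactly in expectation. Per subject, offset ~ N(0.30,
  0.30) log10 µV²/Hz and exponent ~ N(1.20, 0.25) for controls; the
  depressed group's exponent mean is lower by 0.98 of the between-subject
  SD (targeting the strongest reported aperiodic effect), with a small
  per-channel jitter (SD 0.05).
* **Oscillations**: white noise bandpassed with a 4th-order zero-phase
  Butterworth filter (theta: 6 ± 1 Hz; alpha: 10 ± 1.5 Hz), scaled to a
  per-channel variance of `10^logpow` µV². Subject-level log-powers are
  normal with SD 0.3 around region-specific means; depressed means are
  lower by `g_target × SD`, with g_target strongest for parietal theta
  (0.80) and frontal alpha. The alpha-band gaps carry a fixed 1/1.2
  calibration factor: the mapping from generative oscillation log-power to
  the *fitted* periodic band feature has gain ≈ 1.2 in alpha (measured once
  on the full synthesis → Welch → parameterization chain), and the
  generator's contract is about the realized standardized effect. Realized
  effects at study sample sizes: g ≈ 0.79 (parietal theta periodic),
  ≈ 0.90 (frontal alpha periodic), ≈ 0.98 (parietal exponent).
* **Source-level stand-ins**: no inverse solution is simulated. Source
  features are emitted directly as the subject's generative value plus
  independent noise sized so the standardized group gap is attenuated by a
  configurable factor (default 0.5), preserving the electrode-vs-source
  battery structure without claiming source physics.
* **Behavioral scores**: integer BDI-like totals and anhedonia/melancholia
  subscales. Group ranges enforce the inclusion thresholds (controls < 7,
  depressed ≥ 13 on the total). Scores link to a driving generative
  feature (default: parietal theta log-power) through a Gaussian copula on
  rank-normal scores with target Spearman ρ (−0.40 for anhedonia); within
  each group, latent ranks map uniformly onto the group's integer range.
  The *overall* cohort correlation combines this within-group link with
  the group separation itself, so with the default group gaps it lands
  somewhat beyond the within-group target (≈ −0.46 observed); with no
  group gap it attenuates toward ≈ 0.55× the target, because
  between-group pairs carry no rank signal. Integer ties attenuate
  slightly further.
* **Seeding**: one integer seed; per-subject streams are spawned from a
  `SeedSequence` so cohorts are bit-reproducible and subjects independent.

What passing tests on this generator do **not** show about real data: no
eye-blink/EMG artifacts, no nonstationarity, no volume conduction or
channel covariance (channels are independent given the subject), no
knee-shaped spectra, and source features are statistical stand-ins, not
inverse solutions. The generator validates the *pipeline*, not the
neurophysiology.

## Statistics

* **Wilcoxon rank-sum**: midranks; exact enumeration of all rank splits for
  combined n ≤ 12, otherwise the normal approximation with tie-corrected
  variance and a 0.5 continuity correction (type-I error 0.048 at the study
  sizes over 10⁴ null replicates).
* **Hedge's g**: pooled-SD standardized mean difference with small-sample
  correction `J = 1 − 3/(4(n₁+n₂) − 9)`; sign convention HC − MDD, so
  reduced activity in the depressed group is positive.
* **Bonferroni**: `p_adj = min(1, p·m)` with `m` equal to the *designed*
  family size (50 by default) — missing features still count toward the
  family, and subjects missing a value are dropped pairwise per feature,
  never deleted listwise.
* **Demographics**: one-way two-group ANOVA computed in closed form from
  summary statistics (so printed tables are checkable without raw scores),
  and the Pearson 2×2 chi-square without continuity correction.
* **Spearman**: midrank-based, two-sided p via the t-approximation
  (scipy's implementation behind the module surface).

## Classification

Unregularized maximum-likelihood logistic regression fit by IRLS
(convergence when the log-likelihood change < 1e-8; perfect separation is
flagged after the iteration cap — or when training error vanishes — and the
last iterate is returned; a singular weighted design falls back to a tiny
ridge with a warning). MDD is the positive class.

LOSO evaluation standardizes features per fold using training-subject
statistics only (no leakage), and centers each fold's linear score by the
log-odds of its training base rate before pooling. The centering matters:
leaving one subject out shifts the training class balance *against* the
held-out label, so without it an uninformative feature produces pooled
scores that anti-correlate with the labels and a null AUC far below 1/2.
With centering the permutation-null AUC is ≈ 0.5. A residual, well-known
LOSO pessimism remains for *weakly* informative features (leave-one-out
coefficient noise anti-correlates with the held-out subject), which is why
the weakest PSD features can score below chance while all informative
features rank correctly.

AUC is the Mann–Whitney pair statistic (ties ½). Confidence intervals are
percentile bootstrap over subjects, resampled with replacement stratified
by class (n = 1000, seeded); measured coverage ≈ 0.95–0.96 at study sizes.
The feature menu is fixed: five selected single features (periodic and PSD
for parietal theta and frontal alpha, parietal aperiodic exponent), two
within-band pairs, two within-analysis-type pairs, and the 3-feature
periodic + aperiodic combination.

## Problem sizes used in tests and the acceptance script

Unit and acceptance tests run the full chain on reduced montages (6–15
electrodes spanning all five regions, 40 s records) so that Monte-Carlo
repetition stays tractable; the acceptance script runs the complete
60-electrode, 114-subject, 60-s analysis once, plus a 9-electrode 60-subject
cohort for exponent recovery and 100-seed fit-recovery studies. These sizes
are the package's chosen defaults for reproducible desk-scale runs.

## Known limitations

* Knee-mode fitting is implemented and round-trip tested but not exercised
  by the synthetic cohorts (which generate knee-free spectra).
* The exact rank-sum enumeration is O(C(n, n₁)) and restricted to combined
  n ≤ 12; beyond that the tie-corrected normal approximation is used.
* Channel signals are independent within subject; region averaging
  therefore shrinks noise faster than it would under realistic spatial
  correlation.
* EDF files are read (via MNE) but cohorts are written as delimited
  matrices; no EDF writer is bundled.
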
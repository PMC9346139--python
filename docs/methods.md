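# Methods

This note documents the models behind `psilodose`: what each stage assumes,
which parameters matter, what the synthetic generators do and do not
emulate, and where the design was genuinely open.

## Study design being modeled

A within-subject crossover: each participant has one active week (0.5 g
dried *Psilocybe cubensis* in a capsule, dosed twice) and one placebo week
in randomized order, with self-report (21 VAS items on Wed/Thu/Fri/Sat,
dosing on Wed and Fri), questionnaires, creativity and perception/cognition
tasks, daily wristband activity, resting EEG (eyes open/closed) and a
Local-Global auditory session per week. After each week the participant
guesses their condition; the guess's correctness drives the
blinded/unblinded stratification. Analyses are deliberately nonparametric
(Wilcoxon signed-rank, Mann-Whitney U) with Bonferroni correction and JZS
Bayes factors alongside.

## Synthetic data

The generators are pure functions of (config, seed). A master seed expands
into per-component streams via `SeedSequence(seed, spawn_key=(crc32(tag),))`,
so regenerating one table never perturbs another.

**Resting EEG.** Each channel is a 1/f^β Gaussian background (default
β = 1, overall SD 2 µV) plus narrow-band oscillations. A band component is
a sum of sinusoids on every 0.5 Hz FFT bin inside the band with per-bin
amplitude `amp·sqrt(2/K)` (K bins) and phases redrawn every 2 s block, so
the band variance equals `amp²` exactly and an amplitude scale s moves band
power by s² — the analytic anchor used by the tests (0.8² = 0.64, i.e.
−1.94 dB). Defaults (µV): delta 6, theta 5, alpha 6 (×2 with eyes closed),
beta 3, gamma 1.5. The active condition multiplies theta amplitude by
`theta_scale_active` (default 0.8, the direction and rough size of the
study-level finding). Optional artifacts per channel: sparse high-kurtosis
bursts, 50 Hz line noise, or a flat (dead) channel.

Two caveats are intentional properties of this model, not bugs. First,
Hann-taper leakage couples adjacent 0.5 Hz bins, so the strong eyes-closed
alpha component leaks across the 8 Hz edge into the topmost theta bin; the
theta power-*ratio* check therefore uses eyes-open data, while the
band-mean dB shift (a log-domain average over bins) is tested eyes-closed
with a tolerance that absorbs the leakage. Second, per-block phase resets
make the oscillations discontinuous at 2 s boundaries; this is invisible to
the 2 s-epoch periodogram (epochs align with blocks) but adds a small
broadband floor elsewhere.

**Local-Global EEG.** Background is 1/f noise (SD 1 µV per channel). Each
local-deviant trial adds an early Gaussian deflection (peak ≈130 ms after
the fifth tone, 30 ms width) and each global-deviant trial a sustained
plateau (≈300-650 ms post-tone), with peak amplitude `0.2·snr·noise_sd` on
AFz and exponential spatial falloff (length 6 cm) over the montage. This
reproduces the qualitative signature the analysis must detect — a late
sustained global-deviance response, strongest fronto-centrally — not any
particular dipole configuration.

**Study tables.** The ledger assigns random week order and a correct guess
with probability `p_correct_guess` (default 0.735, the active-week rate the
design targets). VAS items are Gaussian noise (baseline 10, SD 10 per item)
clipped to [0, 100]; the configured total effect (default 150 VAS units,
spread evenly over the 21 items) is added only on dosing days of weeks that
are active *and* correctly guessed — the mechanism behind the
blinded/unblinded dissociation. Each item is bounded 0-100, so totals live
in [0, 2100]. Task tables use simple parametric laws with known ground
truth (rivalry durations gamma(2, 1.5) → mean 3.0 s; attentional-blink T2
visibility suppressed at the 300 ms lag only; lognormal RTs; Poisson TMT
errors); activity tables apply a Wednesday dip (×0.7) to steps, distance
and active minutes.

What the generators do **not** emulate: volume conduction and realistic
channel covariance, ICA-separable artifact morphologies (ocular/muscle
topographies), pharmacokinetics/carry-over, non-Gaussian VAS item
distributions, and learning effects across weeks. Passing tests therefore
demonstrate that the *analysis chain* recovers the effects it is built to
detect under controlled conditions — not that it would behave identically
on recorded data.

## Preprocessing

Zero-phase Butterworth filtering (order 4, forward-backward): band-pass
1-90 Hz, band-stop 47.5-52.5 Hz; the measured 50 Hz attenuation exceeds
20 dB and the 10 Hz passband gain is within 5%.

Bad channels: per channel, sample kurtosis and a probability measure (mean
negative log-likelihood of the channel's samples under the pooled
across-channel amplitude histogram, 200 bins) are z-scored across channels;
a channel is rejected when |z| exceeds the dedicated threshold (default 5)
or the ±2.5 SD rule on either measure, and flat channels are rejected
outright as degenerate. Both measures are invariant under channel
reordering and common rescaling. The probability measure is a documented
stand-in for the joint-probability heuristic of common EEG toolboxes; the
exact metric behind the reported rejection counts is not recoverable, so
the contract is behavioral (heavy-tailed channels rejected >95% of the
time, <5% false rejections on i.i.d. channels).

Interpolation replaces a bad channel by the inverse-distance-weighted mean
of its k = 4 nearest good channels on standard 10-20 coordinates (from
MNE's montage tables). This is a deliberate divergence from spherical
splines: fully specifiable in a few lines and adequate at 24 channels.

Epoching is non-overlapping 2 s windows (tail dropped). Epoch rejection —
the original study flagged epochs automatically but confirmed visually,
which is not reproducible — z-scores each epoch's peak amplitude and
variance across epochs per channel and drops epochs exceeding |z| > 5
anywhere, mirroring the channel criteria in spirit.

## Spectra and complexity

LPSD: Hann-tapered periodogram per 2 s epoch (0.5 Hz resolution at 500 Hz),
linear power averaged across kept epochs, then 10·log₁₀. Band values are
the *mean* LPSD over bins in the half-open interval [low, high) — a bin at
exactly 8 Hz belongs to alpha, not theta. The canonical bands are the
default; an alternative set with beta capped at 20 Hz is provided for
figure-style summaries.

LZ76 counts the words of the exhaustive-history parsing (numba kernel,
verified against a naive substring-search oracle). Binarization is a median
split of the z-scored Hilbert envelope of the concatenated kept epochs;
strictly-greater-than ties mean a constant envelope maps to all zeros, and
the split balances symbol counts to within one. The envelope is computed on
the concatenated series (per-epoch computation, available via a flag,
weighs edge effects more heavily on 2 s segments). Normalization is
unspecified in the source analysis; the default divides by the mean count
over 50 seeded shuffles (the convention of the complexity literature this
metric comes from; equals 1 for exchangeable sequences), with n/log₂n
available as `method="asymptotic"`. The global value is the plain mean over
channels. The full pipeline value is exactly invariant under global
amplitude rescaling.

## Local-Global analysis

Sessions are built by constrained sampling and checked by an independent
validator (habituation count, 4-7 deviants, ≥2 standards immediately before
each deviant, ITI grid, pattern bookkeeping, 5 blocks per combination); the
builder rejects its own output if any rule fails. Epochs span [-200,
+1300) ms (750 samples at 500 Hz; sample 0 ↔ -200 ms). ERP processing
order is fixed: trial average → average reference → 0.5-20 Hz zero-phase
band-pass → baseline subtraction over [-200, 0) ms. Habituation trials
never enter contrasts; "local deviant" means fifth tone deviant *and*
global standard, so the two contrast classes are disjoint.

The per-sample test is a paired Wilcoxon signed-rank across subjects
(paired because the design is within-subject; the pooled alternative is a
one-line change), vectorized with the normal approximation plus continuity
correction; zero differences are dropped column-wise and all-tied columns
get p = 1. Runs are maximal stretches of ≥ `run_min` (default 10)
consecutive samples with p < α, reported as half-open sample intervals and
in ms. Because the late global-deviance template begins ≈300 ms after the
fifth tone, recovery is asserted as a run overlapping the >900 ms epoch
window. Under the null the run rate decreases with `run_min`; with
band-limited (autocorrelated) noise the 10-sample rule still admits some
false runs per channel — it is an uncorrected heuristic, reproduced as
such, not a calibrated family-wise error control.

## Statistics

Wilcoxon p-values are exact (no normal approximation) for n ≤ 25 without
ties; zero-difference pairs are dropped and the count recorded.
Mann-Whitney U uses the exact distribution for small samples and the
tie-corrected normal otherwise. Each comparison carries a JZS Bayes factor
computed from the matching t statistic (paired t for within-subject
contrasts; rank tests do not define a Bayes factor, and pairing the rank
test with a t-based JZS factor follows the source analysis), evaluated by
quadrature of the Rouder-style scale-mixture integral after mapping
g = u/(1-u) onto (0, 1); prior scale r = √2/2. Agreement with an
independent high-precision quadrature and with pingouin is tested to 4
significant figures and 0.1% respectively.

Chi-squared on 2×2 tables uses the closed-form statistic with Yates'
continuity correction whenever the `yates` flag is on (default); the flag,
not an expected-count threshold, controls the correction, since the
reference values the package must reproduce apply it at expected counts
of 5. Bonferroni correction is min(1, p·n) with n always recorded.

Blinding stratification comes in two forms: the per-week record partition
(`split_by_blinding`) and the subject-level stratification by the
active-week guess (`split_subjects_by_unblinding`) used for paired
contrasts — a per-week partition would leave almost no subject with both
conditions in the blinded subset (P ≈ 0.07 of guessing both weeks wrong at
the default rate), whereas the subject-level split reproduces the ~25/9
composition the dissociation analysis needs.

Originality scoring reads the group-frequency tiers as f ≤ 1% → 2 points,
1% < f ≤ 5% → 1 point. With small groups the 2-point tier is unreachable
(1% of 34 subjects is less than one subject); this is a property of the
rule, and the tests exercise it with group sizes ≥ 100. Median (not mean)
is the default RT summary, switchable. The psilocybin-equivalent dose
converts psilocin by the molecular-weight ratio 284.25/204.23 (psilocybin
is the phosphorylated prodrug); the raw sum of both masses is reported
alongside, since the conversion convention is not fixed by the source.

## Numerical choices and problem sizes

Simulation-based tests scale the cohort rather than the logic: 20 s
recordings with 4 channels for the theta-recovery sweep (100 seeds × 30
subjects), 6 s recordings for the complexity null (200 seeds, asymptotic
normalization — in a paired within-seed contrast the normalization
constant cancels, and the shuffle default would multiply the cost ×50),
4-block sessions with 6 channels for the ERP recovery sweep (15 seeds × 20
subjects). These sizes were chosen once as the smallest cohorts at which
the paired effects are overwhelmingly detectable and null rates are
estimable; the full 20-block paradigm and 24-channel montage are the
defaults everywhere else.

Degenerate inputs are handled explicitly: constant channels → "degenerate"
rejection; constant envelope → all-zero binarization; all-zero paired
differences → degenerate test result (p undefined, flagged); zero-variance
dominance durations → sample-mean fallback with a flag; fluency 0 →
normalized creativity scores NaN with a flag.

## Known limitations

- Infomax ICA artifact removal is intentionally out of scope; the automatic
  rejection rules are the only cleaning.
- Inverse-distance interpolation underestimates scalp curvature effects
  relative to spherical splines.
- The run-threshold ERP rule is uncorrected by construction.
- The EDF writer targets the plain 16-bit EDF profile (integer sampling
  rate, whole-second records); arbitrary recordings round-trip via the CSV
  dialect, which is exact.
- Synthetic VAS items are additive-Gaussian-then-clip; nothing is claimed
  about the distributional shape of real VAS responses.
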
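# psilodose

Analysis pipeline for a randomized, double-blind, placebo-controlled
crossover study of psilocybin-mushroom microdosing (0.5 g dried
*Psilocybe cubensis* vs. an edible-mushroom placebo, one week per
condition). The package implements the study's full measurement and
statistics chain and ships a synthetic-data module that emulates every
input, so the whole analysis runs end-to-end with no recorded data.

It is written for researchers who want to reuse, audit, or stress-test the
analysis: EEG methodologists (band power, signal complexity, ERP deviance
statistics) and trial statisticians (blinding analysis, nonparametric tests
with Bayes factors).

## What it computes

**Resting-state EEG.** 24-channel 10-20 recordings at 500 Hz are band-pass
(1-90 Hz) and notch (47.5-52.5 Hz) filtered, screened for bad channels by
across-channel kurtosis/probability z-scores (threshold 5, plus a ±2.5 SD
rule), interpolated, cut into 2 s epochs, and cleaned by amplitude/variance
epoch rejection. Log power spectral density (LPSD = 10·log₁₀ P) comes from
Hann-tapered periodograms averaged over epochs and is binned into delta
(1-4), theta (4-8), alpha (8-12), beta (12-30) and gamma (30-40 Hz) bands.
Broadband complexity is Lempel-Ziv: each channel is binarized by a median
split of its z-scored Hilbert envelope (balanced 1/0 counts by
construction) and the LZ76 exhaustive-history word count c(n) is normalized
either by the mean count over 50 random shuffles or by the asymptotic rate
n/log₂n.

**Local-Global auditory ERPs.** Five-tone trials (50 ms tones, 100 ms gaps;
800/1600 Hz) form blocks with 4 habituation trials, then 4-7 global
deviants interleaved with standards (≥2 standards before each deviant),
inter-trial silences on the 1350-1700 ms grid and 15 s block gaps; the four
standard/deviant pattern combinations are each repeated 5 times. Epochs
span -200 to +1300 ms around the first tone; averages are re-referenced to
the channel mean, band-passed 0.5-20 Hz, and baseline-corrected. Contrasts
use a per-sample paired Wilcoxon test with the consecutive-sample rule: an
effect requires ≥10 consecutive samples at p < 0.05.

**Behavioral/statistical layer.** 21-item VAS totals stratified by whether
the participant broke the blind; paired Wilcoxon / Mann-Whitney U tests
with Bonferroni correction (the number of comparisons is always recorded)
and JZS Bayes factors BF10 (Cauchy effect-size prior, scale √2/2; BF10 > 30
"very strong", 1/3-3 inconclusive); chi-squared tests of the per-week
guess-by-condition tables; questionnaire normalization (10·raw/max);
divergent-thinking scoring (fluency, originality by group frequency —
≤1% of the group → 2 points, ≤5% → 1 point — elaboration and repetitions,
each normalized by fluency); gamma-fitted binocular-rivalry dominance
durations; task and wristband-activity summaries; and capsule alkaloid
dose arithmetic.

## Worked example

```python
import numpy as np
from psilodose import synthetic as syn, preprocess as pp, spectral as sp, stats as st

# synthetic eyes-closed recording, active condition (theta amplitude x0.8)
cfg = syn.SyntheticEEGConfig(duration=60.0, seed=42)
rec = syn.gen_resting_eeg(cfg, "active", "closed")
ep = pp.reject_epochs(pp.epoch_recording(pp.filter_recording(rec)))

bands = sp.band_lpsd(sp.compute_lpsd(ep))
print({b: round(float(v.mean()), 2) for b, v in bands.items()})
# {'delta': 9.95, 'theta': 6.69, 'alpha': 15.3, 'beta': -2.57, 'gamma': -6.27}

lz = sp.recording_complexity(ep, method="shuffle", n_shuffles=10, seed=0)
print(round(lz.global_value, 3))
# 0.195

# crossover cohort: unblinding and the dosing-day VAS contrast
design = syn.StudyDesignConfig(seed=42)
ledger = syn.gen_study_ledger(design)
print(st.unblinding_analysis(ledger)["pct_correct_active"])   # 67.6
records = st.vas_scores(syn.gen_vas_records(ledger, design))
unblinded, _ = st.split_subjects_by_unblinding(ledger)
sub = records[records["subject"].isin(unblinded) & records["day"].isin(["Wed", "Fri"])]
wide = sub.groupby(["subject", "condition"])["total"].mean().unstack()
res = st.paired_compare(wide["active"], wide["placebo"]).with_bonferroni(4)
print(f"W={res.statistic:.1f}, p_bonf={res.p_bonferroni:.2e}, BF10={res.bf10:.3g}")
# W=0.0, p_bonf=9.54e-07, BF10=1.68e+09
```

Reading the numbers: alpha dominates the eyes-closed spectrum (15.3 dB);
the global shuffle-normalized Lempel-Ziv value of 0.195 reflects the strong
envelope autocorrelation of band-limited EEG; about two thirds of this
synthetic cohort breaks the blind; and among those subjects the
dosing-day VAS totals are higher under the active dose with overwhelming
evidence (Bonferroni-corrected p ≈ 1e-6, BF10 ≫ 30).

The same stages are available from the shell:

```
psilodose run --seed 1 --out out/            # full synthetic pipeline
psilodose synth --seed 1 --out data/         # tables + example EDF/CSV/session
psilodose spectra --input data/example_eeg.edf --out bands.csv
psilodose lz --input data/example_eeg.csv --method shuffle --n-shuffles 50
psilodose localglobal --seed 1 --alpha 0.05 --run-min 10
psilodose stats --ledger data/ledger.csv --vas data/vas.csv --bonferroni-n 4
```

## Layout

```
src/psilodose/
  synthetic.py    # generators: EEG, Local-Global sessions, study tables
  preprocess.py   # containers, EDF/CSV I/O, filtering, rejection, epoching
  spectral.py     # LPSD, band summaries, LZ76 complexity
  localglobal.py  # session grammar + validator, ERPs, run-threshold rule
  stats.py        # tests, Bayes factors, scoring, summaries, dose arithmetic
  pipeline.py     # orchestration, artifacts, manifest
  cli.py          # `psilodose` command group
docs/methods.md   # models, assumptions, parameter choices, limitations
```
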
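"""Synthetic study data: EEG, Local-Global sessions, and trial tables.

Every generator is a pure function of its configuration and seed, so the
whole pipeline can be exercised end-to-end without any recorded data.  The
generators encode the statistical structure the analysis assumes:

* resting EEG is a 1/f background plus narrow-band oscillations whose
  amplitudes are set per canonical band; the active condition multiplies the
  theta amplitude by ``theta_scale_active`` (the study-level effect is a
  theta-power reduction, i.e. a factor < 1), and eyes-closed recordings get a
  stronger alpha component;
* Local-Global task EEG carries evoked templates time-locked to the fifth
  tone of each trial -- a brief early deflection for local deviants, a
  sustained late (> 300 ms) deflection for global deviants -- strongest on
  the designated fronto-central channel;
* the study ledger gives each subject one active and one placebo week in
  random order, with the week's condition guessed correctly with probability
  ``p_correct_guess``; VAS records carry an additive effect on dosing days
  (Wednesday, Friday) only in weeks that are active *and* correctly guessed.

Band oscillations are synthesized as fixed-amplitude, random-phase sinusoids
on every 0.5 Hz FFT bin inside the band, with phases redrawn per 2 s block.
With ``K`` bins per band and per-bin amplitude ``amp * sqrt(2/K)`` the band
variance equals ``amp**2`` exactly, so an amplitude scale ``s`` moves band
power by ``s**2`` (e.g. 0.8 -> 0.64, i.e. -1.94 dB) -- the analytic
expectation the spectral tests rely on.

A single master seed expands into per-component streams through
``numpy.random.SeedSequence(seed, spawn_key=(crc32(component_tag),))``, so
regenerating one table never perturbs the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import EEGRecording, MONTAGE_24, FRONTOCENTRAL_CHANNEL, montage_positions

__all__ = [
    "BAND_RANGES",
    "VAS_ITEMS",
    "DOSING_DAYS",
    "NON_DOSING_DAYS",
    "SyntheticEEGConfig",
    "StudyDesignConfig",
    "BehavioralTables",
    "gen_resting_eeg",
    "gen_localglobal_eeg",
    "gen_study_ledger",
    "gen_vas_records",
    "gen_behavioral_battery",
    "gen_activity_data",
    "subseed",
]

#: Canonical EEG band edges in Hz (half-open intervals [low, high)).
BAND_RANGES: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma": (30.0, 40.0),
}

#: The 21 acute-effect visual-analog-scale items (0-100 each, total 0-2100).
VAS_ITEMS: tuple[str, ...] = (
    "intensity", "well_being", "anxiety", "imagination", "visual_distortion",
    "spatial_distortion", "time_distortion", "dreamlike", "mind_wandering",
    "sounds_altered", "colors_altered", "body_sensation", "energy",
    "creativity", "focus", "connectedness", "mood_elevation", "irritability",
    "restlessness", "drowsiness", "insight",
)

DOSING_DAYS = ("Wed", "Fri")
NON_DOSING_DAYS = ("Thu", "Sat")
VAS_DAYS = ("Wed", "Thu", "Fri", "Sat")
ACTIVITY_DAYS = ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat")

_ARTIFACT_KINDS = ("burst", "line", "flat")


def subseed(seed: int, tag: str) -> np.random.SeedSequence:
    """Deterministically derive a per-component seed stream from a master
    seed: ``SeedSequence(seed, spawn_key=(crc32(tag),))``."""
    return np.random.SeedSequence(int(seed), spawn_key=(zlib.crc32(tag.encode()),))


# ---------------------------------------------------------------------------
# configurations
# ---------------------------------------------------------------------------

@dataclass
class SyntheticEEGConfig:
    """Generative settings for resting-state EEG.

    ``band_amps`` are oscillation amplitudes in microvolts (band standard
    deviation); ``one_over_f_exponent`` is the spectral slope beta of the
    ``1/f**beta`` background, whose overall standard deviation is
    ``background_amp``.  ``theta_scale_active`` multiplies the theta
    amplitude in the active condition; ``alpha_closed_factor`` multiplies
    alpha when the eyes are closed.
    """

    n_channels: int = 24
    fs: float = 500.0
    duration: float = 300.0
    band_amps: Mapping[str, float] = field(default_factory=lambda: {
        "delta": 6.0, "theta": 5.0, "alpha": 6.0, "beta": 3.0, "gamma": 1.5,
    })
    one_over_f_exponent: float = 1.0
    background_amp: float = 2.0
    theta_scale_active: float = 0.8
    alpha_closed_factor: float = 2.0
    artifact_spec: Sequence[tuple[int | str, str]] | None = None
    seed: int = 0
    block_length: float = 2.0  # phase-reset interval for band oscillations

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration <= 0:
            raise ValueError("fs and duration must be positive")
        bad = set(self.band_amps) - set(BAND_RANGES)
        if bad:
            raise ValueError(f"unknown band name(s) in band_amps: {sorted(bad)}")
        if self.theta_scale_active <= 0:
            raise ValueError("theta_scale_active must be positive")
        if self.artifact_spec:
            for _, kind in self.artifact_spec:
                if kind not in _ARTIFACT_KINDS:
                    raise ValueError(
                        f"unknown artifact kind {kind!r}; expected one of {_ARTIFACT_KINDS}")


@dataclass
class StudyDesignConfig:
    """Trial-design settings for the crossover study tables."""

    n_subjects: int = 34
    p_correct_guess: float = 0.735
    vas_effect_unblinded_active: float = 150.0  # additive shift on VAS totals
    vas_noise_sd: float = 10.0                  # per-item noise, VAS units
    vas_baseline: float = 10.0                  # per-item baseline mean
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_correct_guess <= 1.0:
            raise ValueError("p_correct_guess must be in [0, 1]")
        if self.vas_noise_sd < 0:
            raise ValueError("vas_noise_sd must be non-negative")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be at least 1")


# ---------------------------------------------------------------------------
# resting-state EEG
# ---------------------------------------------------------------------------

def _channel_labels(n_channels: int) -> tuple[str, ...]:
    if n_channels <= len(MONTAGE_24):
        return MONTAGE_24[:n_channels]
    extra = tuple(f"CH{i}" for i in range(len(MONTAGE_24), n_channels))
    return MONTAGE_24 + extra


def _one_over_f(rng: np.random.Generator, n_channels: int, n: int, fs: float,
                exponent: float, amp: float) -> np.ndarray:
    """Gaussian background with power spectral density proportional to
    ``f**-exponent``, normalized to standard deviation ``amp`` per channel."""
    white = rng.standard_normal((n_channels, n))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    shape = np.zeros_like(f)
    shape[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shape, n=n, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return amp * x / sd


def _band_oscillations(rng: np.random.Generator, amps: Mapping[str, float],
                       n_channels: int, n: int, fs: float,
                       block_length: float) -> np.ndarray:
    """Random-phase sinusoids on every FFT bin of each band, phases redrawn
    per block of ``block_length`` seconds."""
    nb = int(round(block_length * fs))
    n_blocks = -(-n // nb)  # ceil
    df = 1.0 / block_length
    freqs = np.fft.rfftfreq(nb, 1.0 / fs)
    spec_amp = np.zeros(freqs.size)
    for name, amp in amps.items():
        if amp == 0:
            continue
        low, high = BAND_RANGES[name]
        in_band = (freqs >= low) & (freqs < high)
        k = int(in_band.sum())
        if k == 0:
            continue
        # per-bin sinusoid amplitude a with K a^2 / 2 = amp^2
        a = amp * np.sqrt(2.0 / k)
        spec_amp[in_band] = a * nb / 2.0  # rfft coefficient magnitude
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(n_blocks, n_channels, freqs.size))
    spec = spec_amp * np.exp(1j * phases)
    spec[..., 0] = 0.0
    if nb % 2 == 0:
        spec[..., -1] = 0.0
    blocks = np.fft.irfft(spec, n=nb, axis=-1)
    out = blocks.transpose(1, 0, 2).reshape(n_channels, n_blocks * nb)
    return out[:, :n]


def _inject_artifacts(data: np.ndarray, labels: Sequence[str],
                      spec: Sequence[tuple[int | str, str]],
                      fs: float, scale: float,
                      rng: np.random.Generator) -> None:
    for chan, kind in spec:
        c = labels.index(chan) if isinstance(chan, str) else int(chan)
        n = data.shape[1]
        if kind == "burst":
            mask = rng.random(n) < 0.002
            data[c, mask] += rng.standard_normal(int(mask.sum())) * 30.0 * scale
        elif kind == "line":
            t = np.arange(n) / fs
            data[c] += 20.0 * scale * np.sin(2 * np.pi * 50.0 * t + rng.uniform(0, 2 * np.pi))
        elif kind == "flat":
            data[c] = 0.0


def gen_resting_eeg(config: SyntheticEEGConfig, condition: str,
                    eyes: str) -> EEGRecording:
    """Generate a resting-state recording for one condition and eyes state.

    The active condition multiplies theta amplitude by
    ``config.theta_scale_active``; eyes-closed multiplies alpha by
    ``config.alpha_closed_factor``.  Identical (config, condition, eyes)
    give bitwise-identical output.
    """
    if condition not in ("active", "placebo"):
        raise ValueError(f"condition must be 'active' or 'placebo', got {condition!r}")
    if eyes not in ("open", "closed"):
        raise ValueError(f"eyes must be 'open' or 'closed', got {eyes!r}")
    rng = np.random.default_rng(subseed(config.seed, f"resting:{condition}:{eyes}"))
    n = int(round(config.fs * config.duration))
    amps = dict(config.band_amps)
    if condition == "active" and "theta" in amps:
        amps["theta"] = amps["theta"] * config.theta_scale_active
    if eyes == "closed" and "alpha" in amps:
        amps["alpha"] = amps["alpha"] * config.alpha_closed_factor

    data = _one_over_f(rng, config.n_channels, n, config.fs,
                       config.one_over_f_exponent, config.background_amp)
    data += _band_oscillations(rng, amps, config.n_channels, n, config.fs,
                               config.block_length)
    labels = _channel_labels(config.n_channels)
    if config.artifact_spec:
        _inject_artifacts(data, labels, config.artifact_spec, config.fs,
                          config.background_amp, rng)
    return EEGRecording(data=data, fs=config.fs, channel_labels=labels,
                        meta={"condition": condition, "eyes": eyes,
                              "seed": config.seed, "synthetic": True})


# ---------------------------------------------------------------------------
# Local-Global task EEG
# ---------------------------------------------------------------------------

def _erp_templates(fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Unit-amplitude evoked templates on a [0, 700) ms axis relative to the
    fifth tone: an early Gaussian deflection (local deviance, peak ~130 ms)
    and a sustained late plateau (global deviance, 300-650 ms)."""
    t = np.arange(int(round(0.7 * fs))) / fs
    local = np.exp(-0.5 * ((t - 0.13) / 0.03) ** 2)
    rise = 1.0 / (1.0 + np.exp(-(t - 0.33) / 0.02))
    fall = 1.0 / (1.0 + np.exp((t - 0.62) / 0.03))
    global_ = rise * fall
    return local, global_


def gen_localglobal_eeg(session, snr: float, seed: int,
                        n_channels: int = 24, fs: float = 500.0,
                        noise_sd: float = 1.0) -> EEGRecording:
    """Simulate task EEG for a Local-Global session.

    Background is 1/f noise of standard deviation ``noise_sd`` per channel.
    Each local-deviant trial adds the early template and each global-deviant
    trial the sustained late template, time-locked to the fifth tone (+600 ms
    from trial onset), with peak amplitude ``0.2 * snr * noise_sd`` on the
    designated fronto-central channel and an exponential spatial falloff.
    """
    if snr < 0:
        raise ValueError("snr must be non-negative")
    trials = session.trials()
    last_onset = max(tr.onset_ms for tr in trials)
    duration_s = (last_onset + 1300.0) / 1000.0 + 0.5
    n = int(round(duration_s * fs))
    rng = np.random.default_rng(subseed(seed, "localglobal-eeg"))
    data = _one_over_f(rng, n_channels, n, fs, 1.0, noise_sd)
    labels = _channel_labels(n_channels)

    # spatial profile: 1 at the designated channel, exponential falloff
    pos = montage_positions([lab for lab in labels if lab in MONTAGE_24])
    full_pos = np.zeros((n_channels, 3))
    full_pos[:pos.shape[0]] = pos
    ref = full_pos[labels.index(FRONTOCENTRAL_CHANNEL)]
    dist = np.linalg.norm(full_pos - ref, axis=1)
    weights = np.exp(-dist / 0.06)

    local_tpl, global_tpl = _erp_templates(fs)
    amp = 0.2 * snr * noise_sd
    for tr in trials:
        start = int(round((tr.onset_ms + 600.0) / 1000.0 * fs))
        stop = min(start + local_tpl.size, n)
        if stop <= start:
            continue
        seg = slice(start, stop)
        m = stop - start
        if tr.local_role == "deviant":
            data[:, seg] += amp * weights[:, None] * local_tpl[None, :m]
        if tr.global_role == "deviant":
            data[:, seg] += amp * weights[:, None] * global_tpl[None, :m]
    return EEGRecording(data=data, fs=fs, channel_labels=labels,
                        meta={"snr": snr, "seed": seed, "synthetic": True,
                              "designated_channel": FRONTOCENTRAL_CHANNEL})


# ---------------------------------------------------------------------------
# study tables
# ---------------------------------------------------------------------------

def gen_study_ledger(config: StudyDesignConfig) -> pd.DataFrame:
    """Crossover ledger: one row per subject and week with the true
    condition, the subject's guess, and its correctness."""
    rng = np.random.default_rng(subseed(config.seed, "ledger"))
    rows = []
    for subj in range(1, config.n_subjects + 1):
        order = ["active", "placebo"]
        if rng.random() < 0.5:
            order.reverse()
        for week, condition in enumerate(order, start=1):
            correct = bool(rng.random() < config.p_correct_guess)
            guess = condition if correct else (
                "placebo" if condition == "active" else "active")
            rows.append({"subject": subj, "week": week, "condition": condition,
                         "guess": guess, "correct": correct})
    return pd.DataFrame(rows)


def gen_vas_records(ledger: pd.DataFrame, config: StudyDesignConfig) -> pd.DataFrame:
    """Per subject x condition x day 21-item VAS records.

    Items are baseline noise clipped to [0, 100]; on dosing days (Wed, Fri)
    of weeks that are active *and* correctly guessed, the configured total
    effect is spread evenly over the 21 items before clipping.
    """
    if ledger.empty:
        raise ValueError("ledger is empty")
    rng = np.random.default_rng(subseed(config.seed, "vas"))
    per_item_effect = config.vas_effect_unblinded_active / len(VAS_ITEMS)
    rows = []
    for _, wk in ledger.iterrows():
        for day in VAS_DAYS:
            items = config.vas_baseline + rng.standard_normal(len(VAS_ITEMS)) * config.vas_noise_sd
            if (wk["condition"] == "active" and wk["correct"]
                    and day in DOSING_DAYS):
                items = items + per_item_effect
            items = np.clip(items, 0.0, 100.0)
            row = {"subject": wk["subject"], "week": wk["week"],
                   "condition": wk["condition"], "day": day}
            row.update({item: items[i] for i, item in enumerate(VAS_ITEMS)})
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class BehavioralTables:
    """Questionnaire, creativity, and task fixtures for one synthetic cohort."""

    questionnaires: pd.DataFrame
    creativity_responses: dict  # task -> {subject: [response, ...]}
    elaboration: pd.DataFrame   # subject, task, elaboration total
    masking: pd.DataFrame
    rivalry: pd.DataFrame
    blink: pd.DataFrame
    gonogo: pd.DataFrame
    stroop: pd.DataFrame
    tmt: pd.DataFrame
    metadata: dict


_QUESTIONNAIRE_MAXIMA = {
    "BFI": 220, "STAI-T": 80, "STAI-S": 80, "SSS": 84, "PANAS": 100,
    "PSS": 56, "TAS": 34, "BIEPS": 39, "MWQ": 30, "FSS": 180,
    "CPS": 30, "TECA": 165, "CFS": 72,
}


def gen_behavioral_battery(ledger: pd.DataFrame, seed: int,
                           rivalry_shape: float = 2.0,
                           rivalry_scale: float = 1.5,
                           blink_dip_lag_ms: int = 300,
                           blink_dip_p: float = 0.45,
                           blink_base_p: float = 0.8,
                           p_unique_response: float = 0.2,
                           ) -> BehavioralTables:
    """Questionnaire scores, creativity response sets, and task trial tables.

    Rivalry dominance durations are gamma(``rivalry_shape``,
    ``rivalry_scale``) so the true mean is their product; the attentional
    blink suppresses T2 visibility at ``blink_dip_lag_ms`` only.  Creativity
    responses mix a small common vocabulary with per-subject unique words.
    """
    if ledger.empty:
        raise ValueError("ledger is empty")
    rng = np.random.default_rng(subseed(seed, "behavior"))
    subjects = sorted(ledger["subject"].unique())
    conditions = ("active", "placebo")

    q_rows = []
    for subj in subjects:
        for cond in conditions:
            for instr, mx in _QUESTIONNAIRE_MAXIMA.items():
                raw = float(np.clip(rng.normal(0.55 * mx, 0.12 * mx), 0, mx))
                q_rows.append({"subject": subj, "condition": cond,
                               "instrument": instr, "raw": raw, "max_score": mx})
    questionnaires = pd.DataFrame(q_rows)

    vocab = [f"common_{i}" for i in range(50)]
    vocab_w = 1.0 / np.arange(1, 51)
    vocab_w /= vocab_w.sum()
    creativity: dict[str, dict[int, list[str]]] = {"AUT": {}, "WK": {}}
    elab_rows = []
    for task in creativity:
        for subj in subjects:
            fluency = int(rng.poisson(10)) + 3
            resp = []
            for k in range(fluency):
                if rng.random() < p_unique_response:
                    resp.append(f"unique_{task}_{subj}_{k}")
                else:
                    resp.append(vocab[rng.choice(50, p=vocab_w)])
            creativity[task][subj] = resp
            elab_rows.append({"subject": subj, "task": task,
                              "elaboration": float(rng.poisson(1.2 * fluency))})
    elaboration = pd.DataFrame(elab_rows)

    soas = (16, 33, 50, 66, 83, 100)
    mask_rows = []
    for subj in subjects:
        for cond in conditions:
            for soa in soas:
                p_obj = 1.0 / (1.0 + np.exp(-(soa - 40.0) / 12.0))
                for _ in range(20):
                    mask_rows.append({
                        "subject": subj, "condition": cond, "soa_ms": soa,
                        "objective_correct": int(rng.random() < p_obj),
                        "subjective_seen": int(rng.random() < p_obj * 0.9),
                    })
    masking = pd.DataFrame(mask_rows)

    riv_rows = []
    for subj in subjects:
        for cond in conditions:
            durs = rng.gamma(rivalry_shape, rivalry_scale, size=40)
            riv_rows += [{"subject": subj, "condition": cond, "duration_s": d}
                         for d in durs]
    rivalry = pd.DataFrame(riv_rows)

    lags = (100, 200, 300, 500, 700)
    blink_rows = []
    for subj in subjects:
        for cond in conditions:
            for lag in lags:
                p2 = blink_dip_p if lag == blink_dip_lag_ms else blink_base_p
                for _ in range(20):
                    t1 = int(rng.random() < 0.9)
                    blink_rows.append({
                        "subject": subj, "condition": cond, "lag_ms": lag,
                        "t1_seen": t1,
                        "t2_seen": int(bool(t1) and rng.random() < p2),
                    })
    blink = pd.DataFrame(blink_rows)

    gng_rows = []
    for subj in subjects:
        for cond in conditions:
            for _ in range(60):
                go = rng.random() < 0.7
                gng_rows.append({
                    "subject": subj, "condition": cond,
                    "trial_type": "go" if go else "nogo",
                    "correct": int(rng.random() < 0.95),
                    "rt_ms": float(rng.lognormal(np.log(400), 0.2)) if go else np.nan,
                })
    gonogo = pd.DataFrame(gng_rows)

    stroop_rows = []
    for subj in subjects:
        for cond in conditions:
            for _ in range(60):
                congruent = rng.random() < 0.5
                base = 500.0 if congruent else 650.0
                stroop_rows.append({
                    "subject": subj, "condition": cond,
                    "congruent": int(congruent),
                    "correct": int(rng.random() < (0.97 if congruent else 0.9)),
                    "rt_ms": float(rng.lognormal(np.log(base), 0.15)),
                })
    stroop = pd.DataFrame(stroop_rows)

    tmt_rows = []
    for subj in subjects:
        for cond in conditions:
            for part, base in (("A", 35.0), ("B", 70.0)):
                tmt_rows.append({
                    "subject": subj, "condition": cond, "part": part,
                    "time_s": float(rng.lognormal(np.log(base), 0.2)),
                    "errors": int(rng.poisson(0.5)),
                })
    tmt = pd.DataFrame(tmt_rows)

    metadata = {
        "rivalry_true_mean": rivalry_shape * rivalry_scale,
        "rivalry_shape": rivalry_shape, "rivalry_scale": rivalry_scale,
        "blink_dip_lag_ms": blink_dip_lag_ms,
        "blink_dip_p": blink_dip_p, "blink_base_p": blink_base_p,
        "seed": seed,
    }
    return BehavioralTables(questionnaires=questionnaires,
                            creativity_responses=creativity,
                            elaboration=elaboration, masking=masking,
                            rivalry=rivalry, blink=blink, gonogo=gonogo,
                            stroop=stroop, tmt=tmt, metadata=metadata)


def gen_activity_data(ledger: pd.DataFrame, seed: int,
                      steps_mean: float = 9000.0, steps_sd: float = 1500.0,
                      km_per_step: float = 0.00075,
                      resting_mean: float = 600.0, resting_sd: float = 60.0,
                      active_mean: float = 180.0, active_sd: float = 40.0,
                      dip_day: str = "Wed", dip_factor: float = 0.7,
                      ) -> pd.DataFrame:
    """Daily wristband activity: steps, distance (km), resting and active
    minutes per subject x weekday x condition, with a configurable mid-week
    dip (dosing-day protocols keep participants seated)."""
    if ledger.empty:
        raise ValueError("ledger is empty")
    rng = np.random.default_rng(subseed(seed, "activity"))
    rows = []
    for _, wk in ledger.iterrows():
        for day in ACTIVITY_DAYS:
            dip = dip_factor if day == dip_day else 1.0
            steps = max(0.0, rng.normal(steps_mean * dip, steps_sd))
            rows.append({
                "subject": wk["subject"], "week": wk["week"],
                "condition": wk["condition"], "weekday": day,
                "steps": steps,
                "distance_km": steps * km_per_step,
                "resting_min": max(0.0, rng.normal(resting_mean, resting_sd)),
                "active_min": max(0.0, rng.normal(active_mean * dip, active_sd)),
            })
    return pd.DataFrame(rows)
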
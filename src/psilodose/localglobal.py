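"""Local-Global auditory oddball sessions and ERP deviance analysis.

A trial is five 50 ms tones separated by 100 ms gaps (tone onsets at 0, 150,
300, 450, 600 ms), each tone low (L, 800 Hz) or high (H, 1600 Hz).  The
fifth tone defines *local* regularity (deviant iff it differs from the first
four); the trial's whole pattern defines *global* regularity relative to the
block's frequent pattern.  Each block opens with 4 habituation trials of the
global-standard pattern, then delivers 4-7 global deviants interleaved with
standards such that at least two standards precede every deviant.  Trials
are separated by silent intervals of 1350-1700 ms in 50 ms steps and blocks
by 15 s; the four standard/deviant pattern combinations are each repeated
``n_repeats`` times (5 by default, giving 20 blocks).

ERP processing follows the fixed order: average across trials, re-reference
to the channel average, zero-phase band-pass 0.5-20 Hz, and baseline-correct
over the 200 ms before the first tone.  Group contrasts use a per-sample
paired Wilcoxon test with the consecutive-sample rule: an effect is declared
only where at least ``run_min`` (default 10) consecutive samples have
p < alpha.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import signal as sps
from scipy import stats as spstats

from .preprocess import EEGRecording, EpochedEEG, reject_epochs

__all__ = [
    "TONE_FREQS",
    "TONE_ONSETS_MS",
    "TRIAL_DURATION_MS",
    "ITI_GRID_MS",
    "PATTERN_COMBOS",
    "LocalGlobalTrial",
    "LocalGlobalBlock",
    "LocalGlobalSession",
    "TrialEpochs",
    "ERPSet",
    "SignificanceMask",
    "build_session",
    "validate_session",
    "extract_trials",
    "deviance_masks",
    "erp_average",
    "paired_wilcoxon_map",
    "find_runs",
    "run_threshold_contrast",
    "render_audio",
]

TONE_FREQS = {"L": 800.0, "H": 1600.0}
TONE_DURATION_MS = 50.0
TONE_GAP_MS = 100.0
TONE_ONSETS_MS = (0.0, 150.0, 300.0, 450.0, 600.0)
TRIAL_DURATION_MS = 650.0
ITI_GRID_MS = tuple(range(1350, 1701, 50))
BLOCK_GAP_MS = 15000.0
SESSION_LEAD_IN_MS = 1000.0  # silence before the first trial (covers the
                             # -200 ms epoch window and filter edges)

#: (global standard, global deviant) pattern pairs; each is used for
#: ``n_repeats`` blocks.  Note a global deviant can be a local standard.
PATTERN_COMBOS = (
    ("LLLLL", "LLLLH"),
    ("LLLLH", "LLLLL"),
    ("HHHHH", "HHHHL"),
    ("HHHHL", "HHHHH"),
)


@dataclass
class LocalGlobalTrial:
    tones: str                 # e.g. "LLLLH"
    local_role: str            # standard | deviant
    global_role: str           # habituation | standard | deviant
    onset_ms: float            # first-tone onset from session start
    iti_before_ms: float | None  # silent gap preceding this trial (None for block start)


@dataclass
class LocalGlobalBlock:
    standard_pattern: str
    deviant_pattern: str
    trials: list[LocalGlobalTrial]


@dataclass
class LocalGlobalSession:
    blocks: list[LocalGlobalBlock]
    n_repeats: int = 5
    block_gap_ms: float = BLOCK_GAP_MS

    def trials(self) -> list[LocalGlobalTrial]:
        return [tr for blk in self.blocks for tr in blk.trials]

    def to_json(self, path) -> Path:
        path = Path(path)
        payload = {"n_repeats": self.n_repeats, "block_gap_ms": self.block_gap_ms,
                   "blocks": [asdict(b) for b in self.blocks]}
        path.write_text(json.dumps(payload, indent=1))
        return path

    @classmethod
    def from_json(cls, path) -> "LocalGlobalSession":
        payload = json.loads(Path(path).read_text())
        blocks = [LocalGlobalBlock(
            standard_pattern=b["standard_pattern"],
            deviant_pattern=b["deviant_pattern"],
            trials=[LocalGlobalTrial(**t) for t in b["trials"]],
        ) for b in payload["blocks"]]
        return cls(blocks=blocks, n_repeats=payload["n_repeats"],
                   block_gap_ms=payload["block_gap_ms"])


def _local_role(pattern: str) -> str:
    return "deviant" if pattern[4] != pattern[3] else "standard"


def build_session(seed: int, n_repeats: int = 5) -> LocalGlobalSession:
    """Construct a rule-conforming session.

    Block order is randomized; within each block the number of global
    deviants is drawn from {4..7} and each deviant is preceded by 2-4
    consecutive standards.  Inter-trial silences are drawn uniformly from
    the 1350-1700 ms grid (50 ms steps).
    """
    from .synthetic import subseed  # local import to avoid a cycle

    rng = np.random.default_rng(subseed(seed, "lg-session"))
    combo_ids = np.repeat(np.arange(4), n_repeats)
    rng.shuffle(combo_ids)
    blocks: list[LocalGlobalBlock] = []
    clock = SESSION_LEAD_IN_MS
    for ci in combo_ids:
        std, dev = PATTERN_COMBOS[ci]
        patterns: list[tuple[str, str]] = [(std, "habituation")] * 4
        n_dev = int(rng.integers(4, 8))
        for _ in range(n_dev):
            for _ in range(int(rng.integers(2, 5))):
                patterns.append((std, "standard"))
            patterns.append((dev, "deviant"))
        trials: list[LocalGlobalTrial] = []
        for k, (pat, role) in enumerate(patterns):
            iti = None if k == 0 else float(rng.choice(ITI_GRID_MS))
            if k > 0:
                clock += TRIAL_DURATION_MS + iti
            trials.append(LocalGlobalTrial(
                tones=pat, local_role=_local_role(pat), global_role=role,
                onset_ms=clock, iti_before_ms=iti))
        blocks.append(LocalGlobalBlock(std, dev, trials))
        clock += TRIAL_DURATION_MS + BLOCK_GAP_MS
    session = LocalGlobalSession(blocks=blocks, n_repeats=n_repeats)
    violations = validate_session(session)
    if violations:  # construction guarantees validity; belt and braces
        raise RuntimeError(f"generated session violates its own rules: {violations}")
    return session


def validate_session(session: LocalGlobalSession) -> list[str]:
    """Check every structural rule; returns an empty list iff all hold.

    Each violation names the block (and trial where relevant) plus a short
    rule tag: ``habituation-count``, ``deviant-count``, ``min-2-standards``,
    ``iti-grid``, ``pattern``, ``tones``, ``block-count``, ``combo-balance``.
    """
    v: list[str] = []
    n_rep = session.n_repeats
    if len(session.blocks) != 4 * n_rep:
        v.append(f"block-count: {len(session.blocks)} blocks, expected {4 * n_rep}")
    counts: dict[tuple[str, str], int] = {}
    for b, blk in enumerate(session.blocks):
        counts[(blk.standard_pattern, blk.deviant_pattern)] = \
            counts.get((blk.standard_pattern, blk.deviant_pattern), 0) + 1
        if (blk.standard_pattern, blk.deviant_pattern) not in PATTERN_COMBOS:
            v.append(f"block {b}: pattern: unknown combination "
                     f"{blk.standard_pattern}/{blk.deviant_pattern}")
        for k, tr in enumerate(blk.trials[:4]):
            if tr.global_role != "habituation" or tr.tones != blk.standard_pattern:
                v.append(f"block {b} trial {k}: habituation-count: first 4 trials "
                         "must be habituation repeats of the global standard")
        n_dev = sum(tr.global_role == "deviant" for tr in blk.trials)
        if not 4 <= n_dev <= 7:
            v.append(f"block {b}: deviant-count: {n_dev} global deviants, expected 4-7")
        since_dev = 0
        for k, tr in enumerate(blk.trials):
            if len(tr.tones) != 5 or any(c not in "LH" for c in tr.tones):
                v.append(f"block {b} trial {k}: tones: bad pattern {tr.tones!r}")
                continue
            if len(set(tr.tones[:4])) != 1:
                v.append(f"block {b} trial {k}: tones: first four tones must be identical")
            if tr.local_role != _local_role(tr.tones):
                v.append(f"block {b} trial {k}: tones: local_role inconsistent "
                         f"with pattern {tr.tones}")
            if tr.global_role == "deviant":
                if tr.tones != blk.deviant_pattern:
                    v.append(f"block {b} trial {k}: pattern: deviant trial with "
                             "non-deviant pattern")
                if since_dev < 2:
                    v.append(f"block {b} trial {k}: min-2-standards: only "
                             f"{since_dev} standards precede this deviant")
                since_dev = 0
            else:
                if tr.tones != blk.standard_pattern:
                    v.append(f"block {b} trial {k}: pattern: standard trial with "
                             "non-standard pattern")
                since_dev += 1
            if k > 0 and tr.iti_before_ms not in ITI_GRID_MS:
                v.append(f"block {b} trial {k}: iti-grid: {tr.iti_before_ms} ms "
                         "not on the 1350-1700/50 grid")
    expected_per_combo = n_rep
    for combo, n in counts.items():
        if combo in PATTERN_COMBOS and n != expected_per_combo:
            v.append(f"combo-balance: {combo[0]}/{combo[1]} used {n} times, "
                     f"expected {expected_per_combo}")
    return v


# ---------------------------------------------------------------------------
# trial extraction and ERP averaging
# ---------------------------------------------------------------------------

EPOCH_WINDOW_S = (-0.2, 1.3)


@dataclass
class TrialEpochs:
    """Per-trial epochs over [-200, +1300) ms relative to the first tone."""

    data: np.ndarray          # trials x channels x samples
    fs: float
    times_ms: np.ndarray
    local_roles: np.ndarray   # str per trial
    global_roles: np.ndarray
    kept_mask: np.ndarray
    channel_labels: tuple[str, ...]


@dataclass
class ERPSet:
    """Trial-averaged waveforms per condition label."""

    erps: dict                # label -> channels x samples (microvolts)
    times_ms: np.ndarray
    n_trials: dict
    fs: float
    channel_labels: tuple[str, ...]
    n_subjects: int = 1


@dataclass
class SignificanceMask:
    """Per-channel/per-sample significance with consecutive-sample runs."""

    pvalues: np.ndarray       # channels x samples
    mask: np.ndarray          # pvalues < alpha
    runs: dict                # channel label -> [(start, end), ...] half-open
    alpha: float
    run_min: int
    times_ms: np.ndarray
    channel_labels: tuple[str, ...]

    def run_times_ms(self, channel: str) -> list[tuple[float, float]]:
        return [(float(self.times_ms[a]), float(self.times_ms[b - 1]))
                for a, b in self.runs.get(channel, [])]


def extract_trials(rec: EEGRecording, session: LocalGlobalSession,
                   reject: bool = True, amp_z: float = 5.0) -> TrialEpochs:
    """Cut per-trial epochs out of a task recording.

    Epochs span [-200, +1300) ms around each trial's first tone (750 samples
    at 500 Hz).  Habituation trials are kept and labeled so downstream
    contrasts can exclude them.  The automatic amplitude/variance epoch
    rejection from the resting-state chain is applied when ``reject``.
    """
    pre, post = EPOCH_WINDOW_S
    n_per = int(round((post - pre) * rec.fs))
    trials = session.trials()
    segs, local_roles, global_roles = [], [], []
    for k, tr in enumerate(trials):
        start = int(round((tr.onset_ms / 1000.0 + pre) * rec.fs))
        stop = start + n_per
        if start < 0 or stop > rec.n_samples:
            raise ValueError(
                f"trial {k} window [{start}, {stop}) outside recording "
                f"of {rec.n_samples} samples")
        segs.append(rec.data[:, start:stop])
        local_roles.append(tr.local_role)
        global_roles.append(tr.global_role)
    data = np.stack(segs)
    kept = np.ones(len(trials), dtype=bool)
    if reject and len(trials) >= 2:
        ep = EpochedEEG(data=data, epoch_length=post - pre, fs=rec.fs,
                        kept_mask=kept, channel_labels=rec.channel_labels)
        kept = reject_epochs(ep, amp_z=amp_z).kept_mask
    times = (np.arange(n_per) / rec.fs + pre) * 1000.0
    return TrialEpochs(data=data, fs=rec.fs, times_ms=times,
                       local_roles=np.array(local_roles),
                       global_roles=np.array(global_roles),
                       kept_mask=kept, channel_labels=rec.channel_labels)


def deviance_masks(trials: TrialEpochs) -> dict[str, np.ndarray]:
    """Kept-trial masks for the two deviance conditions.

    ``global_deviant``: the block's rare pattern.  ``local_deviant``: fifth
    tone differs, but the pattern is the block's frequent one (so the two
    conditions are disjoint).  Habituation trials enter neither.
    """
    kept = trials.kept_mask
    return {
        "global_deviant": kept & (trials.global_roles == "deviant"),
        "local_deviant": kept & (trials.local_roles == "deviant")
        & (trials.global_roles == "standard"),
    }


def erp_average(trials: TrialEpochs, groups: dict[str, np.ndarray] | None = None,
                band: tuple[float, float] = (0.5, 20.0),
                baseline_ms: tuple[float, float] = (-200.0, 0.0)) -> ERPSet:
    """Average trials per group with the fixed processing order:

    1. average across the group's kept trials;
    2. transform to average reference (subtract the per-sample channel mean);
    3. zero-phase band-pass 0.5-20 Hz;
    4. baseline-correct over the 200 ms before the first tone.
    """
    if groups is None:
        groups = deviance_masks(trials)
    sos = sps.butter(4, band, btype="bandpass", fs=trials.fs, output="sos")
    base = (trials.times_ms >= baseline_ms[0]) & (trials.times_ms < baseline_ms[1])
    erps, n_trials = {}, {}
    for name, mask in groups.items():
        if not np.any(mask):
            raise ValueError(f"group {name!r} has no kept trials")
        avg = trials.data[mask].mean(axis=0)
        avg = avg - avg.mean(axis=0, keepdims=True)       # average reference
        avg = sps.sosfiltfilt(sos, avg, axis=1)
        avg = avg - avg[:, base].mean(axis=1, keepdims=True)
        erps[name] = avg
        n_trials[name] = int(mask.sum())
    return ERPSet(erps=erps, times_ms=trials.times_ms, n_trials=n_trials,
                  fs=trials.fs, channel_labels=trials.channel_labels)


# ---------------------------------------------------------------------------
# consecutive-sample significance rule
# ---------------------------------------------------------------------------

def paired_wilcoxon_map(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two-sided paired Wilcoxon signed-rank p-values, vectorized over all
    trailing axes (subjects along axis 0).

    Uses the normal approximation with continuity correction; pairs with
    zero difference are dropped column-wise (classical Wilcoxon policy).
    Columns with no nonzero differences get p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    d = a - b
    flat = d.reshape(d.shape[0], -1)
    absd = np.abs(flat)
    zero = absd == 0.0
    # zeros rank lowest (tied among themselves); nonzeros then occupy ranks
    # n_zero+1 .. S exactly, so subtracting n_zero restores ranks 1..m
    keyed = np.where(zero, -1.0, absd)
    ranks = spstats.rankdata(keyed, axis=0)
    nz = zero.sum(axis=0)
    ranks = ranks - nz[None, :]
    wplus = np.where(flat > 0, ranks, 0.0).sum(axis=0)
    m = flat.shape[0] - nz
    mu = m * (m + 1) / 4.0
    var = m * (m + 1) * (2 * m + 1) / 24.0
    with np.errstate(divide="ignore", invalid="ignore"):
        diff = wplus - mu
        z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var)
    p = 2.0 * spstats.norm.sf(np.abs(z))
    p = np.where(m == 0, 1.0, np.minimum(p, 1.0))
    return p.reshape(d.shape[1:])


def find_runs(below: np.ndarray, run_min: int) -> list[tuple[int, int]]:
    """Maximal runs of True of length >= run_min, as half-open index pairs."""
    below = np.asarray(below, dtype=bool)
    if below.ndim != 1:
        raise ValueError("find_runs expects a 1-D boolean array")
    padded = np.concatenate(([False], below, [False])).astype(int)
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    return [(int(s), int(e)) for s, e in zip(starts, ends) if e - s >= run_min]


def run_threshold_contrast(erps_a: np.ndarray, erps_b: np.ndarray,
                           alpha: float = 0.05, run_min: int = 10,
                           times_ms: np.ndarray | None = None,
                           channel_labels=None) -> SignificanceMask:
    """Consecutive-sample contrast between two per-subject ERP stacks.

    ``erps_a`` and ``erps_b`` are (n_subjects, n_channels, n_samples) with
    matched subject order.  A paired Wilcoxon test is run per channel and
    sample; an effect is reported only where at least ``run_min`` consecutive
    samples have p < alpha.
    """
    erps_a = np.asarray(erps_a, dtype=float)
    erps_b = np.asarray(erps_b, dtype=float)
    if erps_a.shape != erps_b.shape:
        raise ValueError("condition A and B must share (subjects, channels, samples)")
    if erps_a.ndim != 3:
        raise ValueError("expected 3-D (subjects, channels, samples) arrays")
    if erps_a.shape[0] < 6:
        raise ValueError("need at least 6 subjects for the per-sample contrast")
    n_sub, n_ch, n_t = erps_a.shape
    if channel_labels is None:
        channel_labels = tuple(f"ch{c}" for c in range(n_ch))
    if times_ms is None:
        times_ms = np.arange(n_t, dtype=float)
    p = paired_wilcoxon_map(erps_a, erps_b)
    mask = p < alpha
    runs = {lab: find_runs(mask[c], run_min)
            for c, lab in enumerate(channel_labels)}
    return SignificanceMask(pvalues=p, mask=mask, runs=runs, alpha=alpha,
                            run_min=run_min, times_ms=np.asarray(times_ms),
                            channel_labels=tuple(channel_labels))


# ---------------------------------------------------------------------------
# optional audio rendering
# ---------------------------------------------------------------------------

def render_audio(session: LocalGlobalSession, fs: int = 44100,
                 amplitude: float = 0.5) -> np.ndarray:
    """Render a session as a mono waveform (utility; the ERP analysis
    consumes onset metadata, not audio)."""
    trials = session.trials()
    total_s = (max(t.onset_ms for t in trials) + TRIAL_DURATION_MS) / 1000.0 + 0.5
    wave = np.zeros(int(round(total_s * fs)))
    n_tone = int(round(TONE_DURATION_MS / 1000.0 * fs))
    t = np.arange(n_tone) / fs
    env = np.hanning(n_tone)
    for tr in trials:
        for tone, t_on in zip(tr.tones, TONE_ONSETS_MS):
            start = int(round((tr.onset_ms + t_on) / 1000.0 * fs))
            wave[start:start + n_tone] += (
                amplitude * env * np.sin(2 * np.pi * TONE_FREQS[tone] * t))
    return wave
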
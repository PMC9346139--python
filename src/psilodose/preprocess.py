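"""EEG containers, file I/O and the resting-state preprocessing chain.

The chain mirrors a conventional mobile-EEG workflow for a 24-channel 10-20
montage sampled at 500 Hz: zero-phase band-pass (1-90 Hz) and notch
(47.5-52.5 Hz) filtering, statistical bad-channel detection (kurtosis and a
pooled-amplitude probability measure, z-scored across channels),
inverse-distance interpolation of rejected channels on standard scalp
coordinates, segmentation into 2 s epochs, and automatic epoch rejection by
cross-epoch amplitude/variance z-scores.

Recordings are exchanged either as EDF (read through :mod:`mne`, written by a
small built-in 16-bit EDF writer) or as the package CSV dialect: an optional
``#`` metadata line, then a header row ``time_s,<ch1>,<ch2>,...`` and one row
per sample, which round-trips float64 data exactly.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats as spstats

__all__ = [
    "MONTAGE_24",
    "FRONTOCENTRAL_CHANNEL",
    "FormatError",
    "EEGRecording",
    "EpochedEEG",
    "ChannelRejectionReport",
    "read_recording",
    "write_recording",
    "filter_recording",
    "detect_bad_channels",
    "interpolate_channels",
    "epoch_recording",
    "reject_epochs",
    "montage_positions",
]

#: Default 24-channel subset of the standard 10-20 system.  AFz is the
#: designated fronto-central channel used by the Local-Global ERP analysis.
MONTAGE_24: tuple[str, ...] = (
    "Fp1", "Fp2", "AFz", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6", "T7", "C3", "Cz", "C4", "T8",
    "CP1", "CP2", "P3", "Pz", "P4", "O1", "O2",
)

FRONTOCENTRAL_CHANNEL = "AFz"


class FormatError(ValueError):
    """Raised when an EEG file cannot be parsed or written."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class EEGRecording:
    """A multi-channel EEG recording in microvolts.

    Parameters
    ----------
    data
        Array of shape ``(n_channels, n_samples)``.
    fs
        Sampling rate in Hz.
    channel_labels
        10-20 electrode names, one per row of ``data``.
    reference_label
        Name of the (physical) reference electrode.
    meta
        Free-form metadata (subject, condition, eyes state, ...).
    """

    data: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]
    reference_label: str = "FCz"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        self.channel_labels = tuple(self.channel_labels)
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if not np.isfinite(self.data).all():
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs


@dataclass
class EpochedEEG:
    """EEG segmented into fixed-length epochs.

    ``data`` has shape ``(n_epochs, n_channels, n_samples_per_epoch)``;
    ``kept_mask`` flags epochs that survived artifact rejection.
    """

    data: np.ndarray
    epoch_length: float
    fs: float
    kept_mask: np.ndarray
    channel_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("epoched data must be 3-D")
        if self.data.shape[2] != round(self.epoch_length * self.fs):
            raise ValueError("samples per epoch inconsistent with epoch_length * fs")
        self.kept_mask = np.asarray(self.kept_mask, dtype=bool)
        if self.kept_mask.shape != (self.data.shape[0],):
            raise ValueError("kept_mask must have one entry per epoch")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def kept_data(self) -> np.ndarray:
        return self.data[self.kept_mask]


@dataclass
class ChannelRejectionReport:
    """Outcome of statistical bad-channel detection."""

    channel_labels: tuple[str, ...]
    kurtosis_z: np.ndarray
    probability_z: np.ndarray
    rejected: tuple[str, ...]
    reasons: dict
    thresholds: dict


# ---------------------------------------------------------------------------
# montage geometry
# ---------------------------------------------------------------------------

_MONTAGE_CACHE: dict[str, np.ndarray] = {}


def montage_positions(labels) -> np.ndarray:
    """3-D scalp positions (meters) for 10-20 labels, from MNE's standard_1020."""
    missing = [lab for lab in labels if lab not in _montage_table()]
    if missing:
        raise KeyError(f"no standard 10-20 position for channel(s): {missing}")
    return np.array([_montage_table()[lab] for lab in labels])


def _montage_table() -> dict[str, np.ndarray]:
    if not _MONTAGE_CACHE:
        import mne

        try:
            mont = mne.channels.make_standard_montage("colin27_1020")
        except ValueError:  # older MNE: same montage under its previous name
            mont = mne.channels.make_standard_montage("standard_1020")
        _MONTAGE_CACHE.update(mont.get_positions()["ch_pos"])
    return _MONTAGE_CACHE


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_recording(path, fmt: str | None = None) -> EEGRecording:
    """Read an EEG recording from EDF or the package CSV dialect.

    ``fmt`` may be ``"edf"`` or ``"csv"``; when omitted it is inferred from
    the file suffix.
    """
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt == "edf":
        return _read_edf(path)
    if fmt == "csv":
        return _read_csv(path)
    raise FormatError(f"unknown recording format: {fmt!r}")


def write_recording(rec: EEGRecording, path, fmt: str | None = None) -> Path:
    """Write a recording as EDF or as the package CSV dialect."""
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt == "edf":
        _write_edf(rec, path)
    elif fmt == "csv":
        _write_csv(rec, path)
    else:
        raise FormatError(f"unknown recording format: {fmt!r}")
    return path


def _write_csv(rec: EEGRecording, path: Path) -> None:
    t = np.arange(rec.n_samples) / rec.fs
    df = pd.DataFrame({"time_s": t})
    for i, lab in enumerate(rec.channel_labels):
        df[lab] = rec.data[i]
    with open(path, "w") as fh:
        fh.write(f"# psilodose-eeg fs={rec.fs!r} reference={rec.reference_label}\n")
        df.to_csv(fh, index=False)


def _read_csv(path: Path) -> EEGRecording:
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    if path.stat().st_size == 0:
        raise FormatError(f"{path}: empty file")
    fs = None
    reference = "unknown"
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for tok in first[1:].split():
                if tok.startswith("fs="):
                    fs = float(tok[3:])
                elif tok.startswith("reference="):
                    reference = tok[10:]
            body_start = 1
        else:
            body_start = 0
    try:
        df = pd.read_csv(path, skiprows=body_start, float_precision="round_trip")
    except Exception as exc:  # malformed rows, ragged columns ...
        raise FormatError(f"{path}: cannot parse CSV ({exc})") from exc
    if df.shape[1] < 2 or df.columns[0] != "time_s":
        raise FormatError(f"{path}: expected a 'time_s' column followed by channels")
    if df.isna().any().any():
        bad = int(np.flatnonzero(df.isna().any(axis=1).to_numpy())[0]) + body_start + 2
        raise FormatError(f"{path}: missing value near line {bad}")
    t = df["time_s"].to_numpy()
    if fs is None:
        if len(t) < 2:
            raise FormatError(f"{path}: cannot infer sampling rate from one sample")
        fs = float(np.round(1.0 / np.median(np.diff(t)), 6))
    labels = tuple(df.columns[1:])
    data = df.iloc[:, 1:].to_numpy().T
    return EEGRecording(data=data, fs=fs, channel_labels=labels,
                        reference_label=reference)


def _edf_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise FormatError(f"EDF header field too long: {s!r} (max {width})")
    return s.ljust(width).encode("ascii")


def _write_edf(rec: EEGRecording, path: Path) -> None:
    """Minimal EDF writer: 16-bit signals, 1 s data records.

    Requires an integer sampling rate and a whole number of seconds of data
    (use the CSV dialect for arbitrary lengths).
    """
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise FormatError("EDF export requires an integer sampling rate")
    fs = int(round(fs))
    if rec.n_samples % fs != 0:
        raise FormatError("EDF export requires a whole number of seconds of data")
    n_records = rec.n_samples // fs
    ns = rec.n_channels

    # physical range per channel, padded so constant channels stay writable
    pmin = np.floor(rec.data.min(axis=1) * 1000) / 1000 - 0.001
    pmax = np.ceil(rec.data.max(axis=1) * 1000) / 1000 + 0.001
    dig_min, dig_max = -32768, 32767

    hdr = b""
    hdr += _edf_field("0", 8)
    hdr += _edf_field(rec.meta.get("subject", "X"), 80)
    hdr += _edf_field("psilodose", 80)
    hdr += _edf_field("01.01.00", 8)
    hdr += _edf_field("00.00.00", 8)
    hdr += _edf_field(256 * (ns + 1), 8)
    hdr += _edf_field("", 44)
    hdr += _edf_field(n_records, 8)
    hdr += _edf_field(1, 8)
    hdr += _edf_field(ns, 4)

    def sig_fields(values, width):
        return b"".join(_edf_field(v, width) for v in values)

    hdr += sig_fields(rec.channel_labels, 16)
    hdr += sig_fields([""] * ns, 80)
    hdr += sig_fields(["uV"] * ns, 8)
    hdr += sig_fields([f"{v:.8g}"[:8].rstrip(".") for v in pmin], 8)
    hdr += sig_fields([f"{v:.8g}"[:8].rstrip(".") for v in pmax], 8)
    hdr += sig_fields([dig_min] * ns, 8)
    hdr += sig_fields([dig_max] * ns, 8)
    hdr += sig_fields([""] * ns, 80)
    hdr += sig_fields([fs] * ns, 8)
    hdr += sig_fields([""] * ns, 32)
    assert len(hdr) == 256 * (ns + 1)

    # re-parse the physical ranges exactly as a reader will see them
    pmin_r = np.array([float(f"{v:.8g}"[:8].rstrip(".")) for v in pmin])
    pmax_r = np.array([float(f"{v:.8g}"[:8].rstrip(".")) for v in pmax])
    gain = (pmax_r - pmin_r) / (dig_max - dig_min)
    digital = np.round((rec.data - pmin_r[:, None]) / gain[:, None]) + dig_min
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(hdr)
        for r in range(n_records):
            chunk = digital[:, r * fs:(r + 1) * fs]
            fh.write(chunk.tobytes())  # channel-major within a record


def _read_edf(path: Path) -> EEGRecording:
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    if path.stat().st_size == 0:
        raise FormatError(f"{path}: empty file")
    import mne

    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse EDF ({exc})") from exc
    labels = tuple(raw.ch_names)
    for idx, lab in enumerate(labels):
        if not lab.strip():
            raise FormatError(f"{path}: channel {idx} has an empty label")
    data = raw.get_data() * 1e6  # MNE returns volts for uV-dimensioned EDF signals
    return EEGRecording(data=data, fs=float(raw.info["sfreq"]),
                        channel_labels=labels)


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def filter_recording(rec: EEGRecording,
                     band: tuple[float, float] = (1.0, 90.0),
                     notch: tuple[float, float] | None = (47.5, 52.5),
                     order: int = 4) -> EEGRecording:
    """Zero-phase band-pass plus optional band-stop (notch) filtering.

    Butterworth sections applied forward-backward (``sosfiltfilt``), so the
    effective attenuation is twice the single-pass design.  The default
    notch removes 50 Hz mains interference by more than 20 dB.
    """
    low, high = band
    nyq = rec.fs / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(f"band {band} must satisfy 0 < low < high < fs/2 ({nyq})")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    out = sps.sosfiltfilt(sos, rec.data, axis=1)
    if notch is not None:
        nlow, nhigh = notch
        if not (0 < nlow < nhigh < nyq):
            raise ValueError(f"notch {notch} must lie inside (0, fs/2)")
        sos_n = sps.butter(order, [nlow, nhigh], btype="bandstop", fs=rec.fs,
                           output="sos")
        out = sps.sosfiltfilt(sos_n, out, axis=1)
    return replace(rec, data=out)


# ---------------------------------------------------------------------------
# bad-channel detection and interpolation
# ---------------------------------------------------------------------------

def _pooled_nll(data: np.ndarray) -> np.ndarray:
    """Per-channel mean negative log-likelihood under the pooled amplitude
    histogram (200 bins over a robust pooled range).  A channel whose samples
    concentrate where the ensemble rarely goes scores high."""
    pooled = data.ravel()
    lo, hi = np.percentile(pooled, [0.05, 99.95])
    if hi <= lo:
        hi = lo + 1.0
    hist, edges = np.histogram(pooled, bins=200, range=(lo, hi), density=True)
    eps = 1.0 / (pooled.size * (hi - lo))  # < one pooled count per bin
    logp = np.log(np.maximum(hist, eps))
    out = np.empty(data.shape[0])
    for c in range(data.shape[0]):
        idx = np.clip(np.searchsorted(edges, data[c], side="right") - 1, 0, 199)
        out[c] = -logp[idx].mean()
    return out


def detect_bad_channels(rec: EEGRecording, kurt_z: float = 5.0,
                        prob_z: float = 5.0, sd_k: float = 2.5,
                        ) -> ChannelRejectionReport:
    """Flag artifactual channels by across-channel statistics.

    Two measures are computed per channel -- sample kurtosis and the pooled
    amplitude-probability measure -- and z-scored across channels.  A channel
    is rejected when either |z| exceeds its dedicated threshold (``kurt_z``,
    ``prob_z``) or lies beyond ``sd_k`` standard deviations from the
    across-channel mean on either measure.  Constant (flat) channels are
    rejected outright with reason ``"degenerate"`` and excluded from the
    z-score pool.
    """
    if rec.n_channels < 4:
        raise ValueError("bad-channel detection needs at least 4 channels")
    data = rec.data
    sd = data.std(axis=1)
    degenerate = sd == 0.0
    reasons: dict[str, list[str]] = {}

    live = ~degenerate
    kz = np.full(rec.n_channels, np.nan)
    pz = np.full(rec.n_channels, np.nan)
    if live.sum() >= 2:
        kurt = spstats.kurtosis(data[live], axis=1, fisher=True, bias=True)
        nll = _pooled_nll(data[live])
        for vals, out in ((kurt, kz), (nll, pz)):
            mu, sig = vals.mean(), vals.std()
            out[live] = 0.0 if sig == 0 else (vals - mu) / sig

    rejected = []
    for c, lab in enumerate(rec.channel_labels):
        why = []
        if degenerate[c]:
            why.append("degenerate")
        else:
            if abs(kz[c]) > min(kurt_z, sd_k):
                why.append("kurtosis")
            if abs(pz[c]) > min(prob_z, sd_k):
                why.append("probability")
        if why:
            rejected.append(lab)
            reasons[lab] = why
    return ChannelRejectionReport(
        channel_labels=rec.channel_labels,
        kurtosis_z=kz, probability_z=pz,
        rejected=tuple(rejected), reasons=reasons,
        thresholds={"kurt_z": kurt_z, "prob_z": prob_z, "sd_k": sd_k},
    )


def interpolate_channels(rec: EEGRecording, bad, k: int = 4) -> EEGRecording:
    """Replace bad channels by an inverse-distance-weighted average of the
    ``k`` nearest good channels on standard 10-20 scalp coordinates."""
    bad = list(bad)
    if not bad:
        return replace(rec, data=rec.data.copy())
    unknown = [b for b in bad if b not in rec.channel_labels]
    if unknown:
        raise KeyError(f"bad channel(s) not in recording: {unknown}")
    good_idx = [i for i, lab in enumerate(rec.channel_labels) if lab not in bad]
    if not good_idx:
        raise ValueError("cannot interpolate: every channel is bad")
    pos = montage_positions(rec.channel_labels)
    out = rec.data.copy()
    for lab in bad:
        i = rec.channel_labels.index(lab)
        d = np.linalg.norm(pos[good_idx] - pos[i], axis=1)
        order = np.argsort(d)[:k]
        w = 1.0 / np.maximum(d[order], 1e-9)
        w /= w.sum()
        out[i] = w @ rec.data[[good_idx[j] for j in order]]
    return replace(rec, data=out)


# ---------------------------------------------------------------------------
# epoching
# ---------------------------------------------------------------------------

def epoch_recording(rec: EEGRecording, length: float = 2.0) -> EpochedEEG:
    """Cut a recording into consecutive non-overlapping epochs of ``length``
    seconds; the trailing remainder is dropped."""
    nper = int(round(length * rec.fs))
    n_epochs = rec.n_samples // nper
    if n_epochs < 1:
        raise ValueError(
            f"recording ({rec.duration:.3f} s) shorter than epoch length {length} s"
        )
    trimmed = rec.data[:, :n_epochs * nper]
    data = trimmed.reshape(rec.n_channels, n_epochs, nper).transpose(1, 0, 2)
    return EpochedEEG(data=data.copy(), epoch_length=length, fs=rec.fs,
                      kept_mask=np.ones(n_epochs, dtype=bool),
                      channel_labels=rec.channel_labels)


def reject_epochs(ep: EpochedEEG, amp_z: float = 5.0) -> EpochedEEG:
    """Flag epochs whose peak amplitude or variance is an across-epoch outlier.

    For every channel, peak absolute amplitude and variance are z-scored
    across epochs; an epoch is dropped from ``kept_mask`` when any channel
    exceeds ``amp_z`` on either measure.  The data array is left untouched.
    """
    if ep.n_epochs < 2:
        raise ValueError("epoch rejection needs at least 2 epochs")
    peak = np.abs(ep.data).max(axis=2)      # epochs x channels
    var = ep.data.var(axis=2)
    flagged = np.zeros(ep.n_epochs, dtype=bool)
    for feat in (peak, var):
        mu = feat.mean(axis=0)
        sig = feat.std(axis=0)
        sig[sig == 0] = np.inf
        z = (feat - mu) / sig
        flagged |= (np.abs(z) > amp_z).any(axis=1)
    return EpochedEEG(data=ep.data, epoch_length=ep.epoch_length, fs=ep.fs,
                      kept_mask=ep.kept_mask & ~flagged,
                      channel_labels=ep.channel_labels)
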
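"""End-to-end orchestration: synthetic cohort -> preprocessing -> spectra and
complexity -> Local-Global ERPs -> behavioral statistics -> report tables.

``run_pipeline`` executes the stages in order, writes per-stage artifacts
(CSV/JSON) under the output directory, and finishes with a manifest that
echoes every parameter and seed plus SHA-256 digests of the written files,
so a rerun with the same configuration can be verified byte-for-byte on the
deterministic stages.

The default problem sizes (8 EEG subjects, 30 s resting recordings, a
4-block Local-Global session) are chosen so a full synthetic run completes
interactively; the statistical structure does not depend on them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import localglobal as lg
from . import preprocess as pp
from . import spectral as sp
from . import stats as st
from . import synthetic as syn

__all__ = ["RunConfig", "ReportBundle", "run_pipeline", "export_tables"]

log = logging.getLogger("psilodose")


@dataclass
class RunConfig:
    """Parameters of one pipeline run (synthetic mode unless paths given)."""

    out_dir: str = "psilodose_out"
    seed: int = 0
    mode: str = "synthetic"            # synthetic | files
    paths: dict = field(default_factory=dict)

    # cohort
    n_subjects: int = 34
    p_correct_guess: float = 0.735
    vas_effect_unblinded_active: float = 150.0
    vas_noise_sd: float = 10.0

    # EEG stage sizes
    n_eeg_subjects: int = 8
    eeg_duration: float = 30.0
    n_channels: int = 24
    theta_scale_active: float = 0.8

    # preprocessing thresholds
    kurt_z: float = 5.0
    prob_z: float = 5.0
    epoch_len: float = 2.0
    amp_z: float = 5.0

    # complexity
    lz_method: str = "shuffle"
    lz_n_shuffles: int = 10

    # Local-Global
    n_erp_subjects: int = 8
    lg_repeats: int = 1
    lg_snr: float = 5.0
    alpha: float = 0.05
    run_min: int = 10

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**payload)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class ReportBundle:
    """All tables a run produces (figure-ready data, no styling)."""

    ledger: pd.DataFrame
    band_table: pd.DataFrame
    complexity_table: pd.DataFrame
    band_contrasts: pd.DataFrame
    complexity_contrast: st.TestResult
    erp_runs: dict
    vas_results: pd.DataFrame
    unblinding: dict
    task_metrics: pd.DataFrame
    activity: dict
    dose: dict
    manifest: dict


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _preprocess(rec: pp.EEGRecording, cfg: RunConfig) -> pp.EpochedEEG:
    filt = pp.filter_recording(rec)
    report = pp.detect_bad_channels(filt, kurt_z=cfg.kurt_z, prob_z=cfg.prob_z)
    if report.rejected and len(report.rejected) < rec.n_channels:
        filt = pp.interpolate_channels(filt, report.rejected)
    ep = pp.epoch_recording(filt, length=cfg.epoch_len)
    return pp.reject_epochs(ep, amp_z=cfg.amp_z)


def _eeg_stage(cfg: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Resting-state spectra and complexity for the EEG sub-cohort."""
    band_rows, lz_rows = [], []
    for subj in range(1, cfg.n_eeg_subjects + 1):
        eeg_cfg = syn.SyntheticEEGConfig(
            n_channels=cfg.n_channels, duration=cfg.eeg_duration,
            theta_scale_active=cfg.theta_scale_active,
            seed=int(np.random.default_rng(
                syn.subseed(cfg.seed, f"eeg-subject:{subj}")).integers(2 ** 31)),
        )
        for condition in ("active", "placebo"):
            for eyes in ("open", "closed"):
                rec = syn.gen_resting_eeg(eeg_cfg, condition, eyes)
                ep = _preprocess(rec, cfg)
                bands = sp.band_lpsd(sp.compute_lpsd(ep))
                for band, vals in bands.items():
                    for ch, v in zip(ep.channel_labels, vals):
                        band_rows.append({"subject": subj, "condition": condition,
                                          "eyes": eyes, "channel": ch,
                                          "band": band, "lpsd_db": v})
                res = sp.recording_complexity(
                    ep, method=cfg.lz_method, n_shuffles=cfg.lz_n_shuffles,
                    seed=cfg.seed)
                lz_rows.append({"subject": subj, "condition": condition,
                                "eyes": eyes, "metric": "lz_global",
                                "value": res.global_value})
                for ch, v in zip(ep.channel_labels, res.channel_values):
                    lz_rows.append({"subject": subj, "condition": condition,
                                    "eyes": eyes, "metric": f"lz_{ch}",
                                    "value": v})
    return pd.DataFrame(band_rows), pd.DataFrame(lz_rows)


def _band_contrasts(band_table: pd.DataFrame) -> pd.DataFrame:
    """Paired active-vs-placebo contrasts per eyes state and band, on the
    channel-mean LPSD, Bonferroni-corrected over the bands tested."""
    rows = []
    mean_band = (band_table.groupby(["subject", "condition", "eyes", "band"])
                 ["lpsd_db"].mean().reset_index())
    n_bands = mean_band["band"].nunique()
    for (eyes, band), sub in mean_band.groupby(["eyes", "band"]):
        wide = sub.pivot(index="subject", columns="condition", values="lpsd_db")
        res = st.paired_compare(wide["active"], wide["placebo"],
                                name=f"{eyes}-{band}")
        res.with_bonferroni(n_bands)
        rows.append({"eyes": eyes, "band": band, "statistic": res.statistic,
                     "p": res.p, "p_bonferroni": res.p_bonferroni,
                     "bf10": res.bf10, "n": res.n,
                     "mean_diff_db": float((wide["active"] - wide["placebo"]).mean())})
    return pd.DataFrame(rows)


def _erp_stage(cfg: RunConfig) -> dict:
    """Local-Global deviance contrast across the ERP sub-cohort."""
    global_stack, local_stack = [], []
    labels = times = None
    for subj in range(1, cfg.n_erp_subjects + 1):
        sub_seed = int(np.random.default_rng(
            syn.subseed(cfg.seed, f"erp-subject:{subj}")).integers(2 ** 31))
        session = lg.build_session(sub_seed, n_repeats=cfg.lg_repeats)
        rec = syn.gen_localglobal_eeg(session, snr=cfg.lg_snr, seed=sub_seed,
                                      n_channels=cfg.n_channels)
        trials = lg.extract_trials(rec, session)
        erps = lg.erp_average(trials)
        global_stack.append(erps.erps["global_deviant"])
        local_stack.append(erps.erps["local_deviant"])
        labels, times = erps.channel_labels, erps.times_ms
    mask = lg.run_threshold_contrast(
        np.stack(global_stack), np.stack(local_stack), alpha=cfg.alpha,
        run_min=cfg.run_min, times_ms=times, channel_labels=labels)
    return {
        "alpha": cfg.alpha, "run_min": cfg.run_min,
        "n_subjects": cfg.n_erp_subjects,
        "runs_ms": {ch: mask.run_times_ms(ch)
                    for ch, r in mask.runs.items() if r},
        "designated_channel": pp.FRONTOCENTRAL_CHANNEL,
    }


def _vas_stage(ledger: pd.DataFrame, cfg: RunConfig,
               design: syn.StudyDesignConfig) -> tuple[pd.DataFrame, dict]:
    records = st.vas_scores(syn.gen_vas_records(ledger, design))
    unblinded_ids, blinded_ids = st.split_subjects_by_unblinding(ledger)
    unblinded = records[records["subject"].isin(unblinded_ids)]
    blinded = records[records["subject"].isin(blinded_ids)]
    rows = []
    for subset_name, subset in (("unblinded", unblinded), ("blinded", blinded),
                                ("all", records)):
        for day in syn.VAS_DAYS:
            sub = subset[subset["day"] == day]
            wide = sub.pivot_table(index="subject", columns="condition",
                                   values="total")
            if ("active" not in wide.columns or "placebo" not in wide.columns):
                continue
            both = wide.dropna()
            if len(both) < 4:
                continue
            res = st.paired_compare(both["active"], both["placebo"],
                                    name=f"vas-{subset_name}-{day}")
            res.with_bonferroni(len(syn.VAS_DAYS))
            rows.append({"subset": subset_name, "day": day,
                         "dosing_day": day in syn.DOSING_DAYS,
                         "statistic": res.statistic, "p": res.p,
                         "p_bonferroni": res.p_bonferroni, "bf10": res.bf10,
                         "bf_category": (st.bf_category(res.bf10)
                                         if res.bf10 else None),
                         "n": len(both), "degenerate": res.degenerate})
    unblinding = st.unblinding_analysis(ledger)
    return pd.DataFrame(rows), unblinding


def run_pipeline(cfg: RunConfig) -> ReportBundle:
    """Execute every stage and write artifacts + manifest under
    ``cfg.out_dir``.  Identical configurations give identical manifests for
    the deterministic stages."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("pipeline start: seed=%d out=%s", cfg.seed, out)

    design = syn.StudyDesignConfig(
        n_subjects=cfg.n_subjects, p_correct_guess=cfg.p_correct_guess,
        vas_effect_unblinded_active=cfg.vas_effect_unblinded_active,
        vas_noise_sd=cfg.vas_noise_sd, seed=cfg.seed)

    stage = "ledger"
    try:
        ledger = syn.gen_study_ledger(design)
        stage = "eeg"
        log.info("EEG stage: %d subjects x %g s", cfg.n_eeg_subjects,
                 cfg.eeg_duration)
        band_table, lz_table = _eeg_stage(cfg)
        band_contrasts = _band_contrasts(band_table)
        lz_global = lz_table[lz_table["metric"] == "lz_global"]
        wide = lz_global.pivot_table(index=["subject", "eyes"],
                                     columns="condition", values="value")
        complexity_contrast = st.paired_compare(
            wide["active"], wide["placebo"], name="lz-global")
        stage = "localglobal"
        log.info("Local-Global stage: %d subjects, snr=%g", cfg.n_erp_subjects,
                 cfg.lg_snr)
        erp_runs = _erp_stage(cfg)
        stage = "behavior"
        vas_results, unblinding = _vas_stage(ledger, cfg, design)
        battery = syn.gen_behavioral_battery(ledger, seed=cfg.seed)
        task_metrics = st.summarize_tasks(battery)
        activity = st.summarize_activity(syn.gen_activity_data(ledger, cfg.seed))
        dose = st.capsule_alkaloid_mass()
    except Exception:
        log.exception("pipeline aborted in stage %r", stage)
        raise

    bundle = ReportBundle(
        ledger=ledger, band_table=band_table, complexity_table=lz_table,
        band_contrasts=band_contrasts, complexity_contrast=complexity_contrast,
        erp_runs=erp_runs, vas_results=vas_results, unblinding=unblinding,
        task_metrics=task_metrics, activity=activity, dose=dose,
        manifest={"config": cfg.to_dict()})
    export_tables(bundle, out)
    return bundle


def _jsonable(obj):
    if isinstance(obj, st.TestResult):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def export_tables(bundle: ReportBundle, out_dir, formats=("csv", "json")) -> list[Path]:
    """Write the bundle's tables as CSV and its reports as JSON, then the
    manifest with SHA-256 digests of everything written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    unknown = set(formats) - {"csv", "json"}
    if unknown:
        raise ValueError(f"unknown export format(s): {sorted(unknown)}")
    written: list[Path] = []
    if "csv" in formats:
        for name, df in (("ledger", bundle.ledger),
                         ("band_table", bundle.band_table),
                         ("complexity_table", bundle.complexity_table),
                         ("band_contrasts", bundle.band_contrasts),
                         ("vas_results", bundle.vas_results),
                         ("task_metrics", bundle.task_metrics)):
            path = out / f"{name}.csv"
            df.to_csv(path, index=False)
            written.append(path)
    if "json" in formats:
        reports = {
            "erp_runs": bundle.erp_runs,
            "unblinding": bundle.unblinding,
            "complexity_contrast": bundle.complexity_contrast,
            "dose": bundle.dose,
            "activity_contrasts": bundle.activity["contrasts"],
        }
        for name, payload in reports.items():
            path = out / f"{name}.json"
            path.write_text(json.dumps(_jsonable(payload), indent=1))
            written.append(path)
    manifest = dict(bundle.manifest)
    manifest["artifacts"] = {p.name: _sha256(p) for p in written}
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(_jsonable(manifest), indent=1))
    bundle.manifest = manifest
    return written + [mpath]
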
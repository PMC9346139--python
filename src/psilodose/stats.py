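"""The trial's statistical layer.

Covers VAS scoring with the blinded/unblinded stratification, paired and
unpaired nonparametric comparisons (each carrying a JZS Bayes factor
computed from the matching t statistic), Bonferroni correction with the
comparison count recorded, chi-squared tests of the unblinding contingency
tables, questionnaire normalization, divergent-thinking (fluency /
originality / elaboration) scoring, gamma fits of binocular-rivalry
dominance durations, task and activity summaries, and capsule dose
arithmetic.

The JZS Bayes factor BF10 is the evidence ratio for the alternative under a
Cauchy effect-size prior of scale r (default sqrt(2)/2), evaluated by
numerical quadrature of the scale-mixture integral; BF10 > 30 counts as
very strong evidence and values between 1/3 and 3 as inconclusive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate
from scipy import stats as spstats

from .synthetic import VAS_ITEMS, DOSING_DAYS, NON_DOSING_DAYS

__all__ = [
    "TestResult",
    "GammaFit",
    "vas_scores",
    "split_by_blinding",
    "split_subjects_by_unblinding",
    "paired_compare",
    "unpaired_compare",
    "jzs_bf10",
    "bf_category",
    "bonferroni_adjust",
    "chi2_independence",
    "unblinding_analysis",
    "normalize_questionnaire",
    "score_divergent",
    "fit_gamma_dominance",
    "summarize_tasks",
    "summarize_activity",
    "capsule_alkaloid_mass",
    "PSILOCYBIN_MW",
    "PSILOCIN_MW",
    "DEFAULT_ALKALOID_CONCENTRATIONS",
]

PSILOCYBIN_MW = 284.25  # g/mol
PSILOCIN_MW = 204.23    # g/mol

#: LC-MS alkaloid concentrations of the study capsules, ug per g dry weight.
DEFAULT_ALKALOID_CONCENTRATIONS = {
    "psilocybin": 640.2, "psilocin": 950.7,
    "baeocystin": 50.4, "norbaeocystin": 12.5,
}


@dataclass
class TestResult:
    """One statistical comparison with its correction/Bayes metadata."""

    name: str
    statistic: float
    p: float
    n: int
    n2: int | None = None
    paired: bool = True
    bf10: float | None = None
    p_bonferroni: float | None = None
    n_comparisons: int | None = None
    degenerate: bool = False
    notes: dict = field(default_factory=dict)

    def with_bonferroni(self, n_comparisons: int) -> "TestResult":
        self.n_comparisons = n_comparisons
        self.p_bonferroni = (None if math.isnan(self.p)
                             else bonferroni_adjust(self.p, n_comparisons))
        return self


# ---------------------------------------------------------------------------
# VAS scoring and blinding stratification
# ---------------------------------------------------------------------------

def vas_scores(records: pd.DataFrame) -> pd.DataFrame:
    """Attach the 21-item total to each subject/condition/day record.

    Returns the input with a ``total`` column and a ``dosing_day`` flag
    (Wednesday and Friday are dosing days).  Missing items raise, naming
    the offending subject/day rows.
    """
    missing = [it for it in VAS_ITEMS if it not in records.columns]
    if missing:
        raise ValueError(f"records are missing VAS item column(s): {missing}")
    item_block = records[list(VAS_ITEMS)]
    if item_block.isna().any().any():
        where = records.loc[item_block.isna().any(axis=1), ["subject", "day"]]
        raise ValueError(f"missing VAS item values for:\n{where.to_string(index=False)}")
    out = records.copy()
    out["total"] = item_block.sum(axis=1)
    out["dosing_day"] = out["day"].isin(DOSING_DAYS)
    return out


def split_by_blinding(ledger: pd.DataFrame, records: pd.DataFrame,
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition records into (unblinded, blinded) by the ledger's
    correctness flag for each record's subject and week."""
    key = ledger.set_index(["subject", "week"])["correct"]
    idx = pd.MultiIndex.from_frame(records[["subject", "week"]])
    unmatched = idx[~idx.isin(key.index)]
    if len(unmatched):
        raise KeyError(f"records without a ledger row: {list(unmatched[:5])}")
    correct = key.loc[idx].to_numpy()
    return records[correct].copy(), records[~correct].copy()


def split_subjects_by_unblinding(ledger: pd.DataFrame) -> tuple[list, list]:
    """Subject-level stratification for the paired active-vs-placebo
    contrasts: a subject is *unblinded* when their active week was guessed
    correctly, *blinded* otherwise.  (The per-week partition of
    :func:`split_by_blinding` leaves almost no subject with both conditions
    in the blinded subset, so within-subject contrasts stratify by the
    active-week guess.)"""
    active = ledger[ledger["condition"] == "active"]
    unblinded = sorted(active.loc[active["correct"], "subject"].unique())
    blinded = sorted(active.loc[~active["correct"].astype(bool), "subject"].unique())
    return unblinded, blinded


# ---------------------------------------------------------------------------
# nonparametric comparisons with JZS Bayes factors
# ---------------------------------------------------------------------------

def paired_compare(x, y, name: str = "paired") -> TestResult:
    """Paired Wilcoxon signed-rank test with an attached JZS Bayes factor.

    Pairs with zero difference are dropped (classical Wilcoxon policy;
    recorded in ``notes``).  Exact p-values are used for n <= 25 without
    ties, the normal approximation otherwise.  The Bayes factor comes from
    the paired t statistic on the full data.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    nz = d != 0
    m = int(nz.sum())
    if m == 0:
        return TestResult(name=name, statistic=np.nan, p=np.nan, n=len(x),
                          paired=True, degenerate=True,
                          notes={"reason": "all differences zero"})
    if m < 3:
        raise ValueError("need at least 3 nonzero differences")
    dd = d[nz]
    has_ties = len(np.unique(np.abs(dd))) < len(dd)
    method = "exact" if (m <= 25 and not has_ties) else "approx"
    stat, p = spstats.wilcoxon(dd, method=method)
    tstat = spstats.ttest_rel(x, y).statistic
    bf = jzs_bf10(float(tstat), len(x)) if np.isfinite(tstat) else None
    return TestResult(name=name, statistic=float(stat), p=float(p), n=len(x),
                      paired=True, bf10=bf,
                      notes={"zero_pairs_dropped": len(x) - m,
                             "p_method": method})


def unpaired_compare(x, y, name: str = "unpaired") -> TestResult:
    """Mann-Whitney U test (two-sided) with a two-sample JZS Bayes factor."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    res = spstats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    bf = None
    if len(x) >= 2 and len(y) >= 2:
        tstat = spstats.ttest_ind(x, y).statistic
        if np.isfinite(tstat):
            bf = jzs_bf10(float(tstat), len(x), len(y))
    return TestResult(name=name, statistic=float(res.statistic),
                      p=float(res.pvalue), n=len(x), n2=len(y), paired=False,
                      bf10=bf)


def jzs_bf10(t: float, n1: int, n2: int | None = None,
             r: float = math.sqrt(2) / 2.0) -> float:
    """JZS Bayes factor for a t statistic.

    One-sample/paired when ``n2`` is None (effective n = n1, df = n1 - 1),
    two-sample otherwise (effective n = n1*n2/(n1+n2), df = n1 + n2 - 2).
    The scale-mixture integral over the prior on the effect-size variance is
    evaluated on (0, 1) after the change of variables g = u/(1-u).
    """
    if not np.isfinite(t):
        raise ValueError("t statistic must be finite")
    if n2 is None:
        if n1 < 2:
            raise ValueError("need n >= 2")
        n_eff, df = float(n1), n1 - 1
    else:
        if n1 < 2 or n2 < 2:
            raise ValueError("need n1, n2 >= 2")
        n_eff, df = n1 * n2 / (n1 + n2), n1 + n2 - 2

    t2 = t * t

    def integrand(u: float) -> float:
        g = u / (1.0 - u)
        jac = 1.0 / ((1.0 - u) * (1.0 - u))
        a = 1.0 + n_eff * g * r * r
        val = (a ** -0.5
               * (1.0 + t2 / (a * df)) ** (-(df + 1) / 2.0)
               * (2.0 * math.pi) ** -0.5
               * g ** -1.5 * math.exp(-1.0 / (2.0 * g)))
        return val * jac

    integral, _ = integrate.quad(integrand, 0.0, 1.0, limit=200)
    null_like = (1.0 + t2 / df) ** (-(df + 1) / 2.0)
    return integral / null_like


_BF_BANDS = (
    (100.0, "extreme"), (30.0, "very strong"), (10.0, "strong"),
    (3.0, "moderate"),
)


def bf_category(bf10: float) -> str:
    """Verbal evidence category: > 30 is 'very strong' for the alternative,
    1/3-3 is 'inconclusive', with the reciprocal bands favoring the null."""
    if bf10 <= 0:
        raise ValueError("bf10 must be positive")
    for cut, label in _BF_BANDS:
        if bf10 > cut:
            return label
    if bf10 >= 1.0 / 3.0:
        return "inconclusive"
    for cut, label in _BF_BANDS:
        if bf10 < 1.0 / cut:
            return f"{label} (null)"
    return "moderate (null)"


def bonferroni_adjust(p: float, n_comparisons: int) -> float:
    """min(1, p * n); the comparison count travels with the result."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    return min(1.0, p * n_comparisons)


def chi2_independence(table, yates: bool = True) -> TestResult:
    """Chi-squared independence test on a 2x2 contingency table (1 df),
    with Yates' continuity correction when ``yates``."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("expected a 2x2 table of nonnegative counts")
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n = table.sum()
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("contingency table has a zero margin")
    (a, b), (c, d) = table
    det = abs(a * d - b * c)
    if yates:
        det = max(det - n / 2.0, 0.0)
    stat = n * det * det / (rows[0] * rows[1] * cols[0] * cols[1])
    p = float(spstats.chi2.sf(stat, df=1))
    return TestResult(name="chi2_independence", statistic=float(stat), p=p,
                      n=int(n), paired=False,
                      notes={"yates": yates, "df": 1})


# ---------------------------------------------------------------------------
# unblinding
# ---------------------------------------------------------------------------

def unblinding_analysis(ledger: pd.DataFrame, yates: bool = True) -> dict:
    """Unblinding rates and per-week guess-by-condition chi-squared tests.

    Percentages are rounded to one decimal (25 of 34 active weeks -> 73.5).
    """
    if ledger.empty:
        raise ValueError("ledger is empty")

    def pct(sub: pd.DataFrame) -> float:
        return round(100.0 * sub["correct"].mean(), 1) if len(sub) else float("nan")

    report = {
        "pct_correct_active": pct(ledger[ledger["condition"] == "active"]),
        "pct_correct_placebo": pct(ledger[ledger["condition"] == "placebo"]),
        "pct_correct_overall": pct(ledger),
        "n_weeks": int(len(ledger)),
        "weeks": {},
    }
    for week, sub in ledger.groupby("week"):
        tab = np.zeros((2, 2))
        for _, row in sub.iterrows():
            i = 0 if row["guess"] == "active" else 1
            j = 0 if row["condition"] == "active" else 1
            tab[i, j] += 1
        entry = {"table": tab, "pct_correct": pct(sub)}
        try:
            entry["chi2"] = chi2_independence(tab, yates=yates)
        except ValueError as exc:  # degenerate margin (e.g. everyone guessed active)
            entry["chi2"] = None
            entry["chi2_error"] = str(exc)
        report["weeks"][int(week)] = entry
    return report


# ---------------------------------------------------------------------------
# questionnaires and creativity
# ---------------------------------------------------------------------------

def normalize_questionnaire(raw: float, max_score: float) -> float:
    """Scale a raw score by its maximum possible value onto [0, 10]."""
    if max_score <= 0:
        raise ValueError("max_score must be positive")
    if raw < 0 or raw > max_score:
        raise ValueError(f"raw score {raw} outside [0, {max_score}]")
    return 10.0 * raw / max_score


def score_divergent(responses: dict, elaboration: dict | None = None,
                    ) -> pd.DataFrame:
    """Score a divergent-thinking task from the whole group's responses.

    ``responses`` maps subject -> list of responses (strings).  Per subject:
    fluency = number of responses; each response earns 2 points if given by
    at most 1% of the group, 1 point if by more than 1% but at most 5%, and
    0 otherwise (group frequency = fraction of subjects who gave it);
    originality = sum of points; repetitions = within-subject duplicates.
    Originality, elaboration and repetitions are also returned divided by
    fluency; a fluency of zero leaves them NaN with ``degenerate`` set.
    """
    if len(responses) < 2:
        raise ValueError("group scoring needs at least 2 subjects")
    n_group = len(responses)
    givers: dict[str, int] = {}
    normalized = {s: [str(r).strip().casefold() for r in resp]
                  for s, resp in responses.items()}
    for resp in normalized.values():
        for r in set(resp):
            givers[r] = givers.get(r, 0) + 1

    def points(r: str) -> int:
        f = givers[r] / n_group
        if f <= 0.01:
            return 2
        if f <= 0.05:
            return 1
        return 0

    rows = []
    for subj, resp in normalized.items():
        fluency = len(resp)
        originality = sum(points(r) for r in resp)
        repetitions = fluency - len(set(resp))
        elab = float(elaboration.get(subj, 0.0)) if elaboration else 0.0
        degenerate = fluency == 0
        denom = fluency if fluency else np.nan
        rows.append({
            "subject": subj, "fluency": fluency, "originality": originality,
            "elaboration": elab, "repetitions": repetitions,
            "originality_per_fluency": originality / denom,
            "elaboration_per_fluency": elab / denom,
            "repetitions_per_fluency": repetitions / denom,
            "degenerate": degenerate,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# perception/cognition task metrics
# ---------------------------------------------------------------------------

@dataclass
class GammaFit:
    """Maximum-likelihood gamma fit of dominance durations."""

    shape: float
    scale: float
    mean: float
    fallback: bool = False


def fit_gamma_dominance(durations) -> GammaFit:
    """Fit a gamma law to rivalry dominance durations; mean = shape*scale.

    Degenerate (zero-variance) samples fall back to the sample mean with the
    ``fallback`` flag set.
    """
    durations = np.asarray(durations, dtype=float)
    if durations.size < 10:
        raise ValueError("need at least 10 dominance durations")
    if (durations <= 0).any():
        raise ValueError("dominance durations must be positive")
    if durations.std() == 0.0:
        m = float(durations.mean())
        return GammaFit(shape=np.nan, scale=np.nan, mean=m, fallback=True)
    shape, _, scale = spstats.gamma.fit(durations, floc=0.0)
    return GammaFit(shape=float(shape), scale=float(scale),
                    mean=float(shape * scale))


def _median_rt(sub: pd.DataFrame, rt_summary: str) -> float:
    rts = sub["rt_ms"].dropna()
    if rts.empty:
        return np.nan
    return float(rts.median() if rt_summary == "median" else rts.mean())


def summarize_tasks(tables, rt_summary: str = "median") -> pd.DataFrame:
    """Per subject/condition metrics for the perception & cognition battery.

    Backward masking: objective and subjective accuracy per SOA.  Attentional
    blink: T1 visibility and T2-given-T1 visibility per lag.  Rivalry: mean
    dominance duration from the gamma fit.  Go/NoGo and Stroop: accuracy and
    median RT (Stroop split by congruency).  TMT: completion time and errors
    per part.  Returns a tidy frame (subject, condition, task, metric, value).
    """
    if rt_summary not in ("median", "mean"):
        raise ValueError("rt_summary must be 'median' or 'mean'")
    rows = []

    def add(subj, cond, task, metric, value):
        rows.append({"subject": subj, "condition": cond, "task": task,
                     "metric": metric, "value": float(value)})

    for (subj, cond, soa), sub in tables.masking.groupby(
            ["subject", "condition", "soa_ms"]):
        add(subj, cond, "masking", f"objective_acc_soa{int(soa)}",
            sub["objective_correct"].mean())
        add(subj, cond, "masking", f"subjective_acc_soa{int(soa)}",
            sub["subjective_seen"].mean())

    for (subj, cond), sub in tables.rivalry.groupby(["subject", "condition"]):
        add(subj, cond, "rivalry", "mean_dominance_s",
            fit_gamma_dominance(sub["duration_s"].to_numpy()).mean)

    for (subj, cond, lag), sub in tables.blink.groupby(
            ["subject", "condition", "lag_ms"]):
        add(subj, cond, "blink", f"t1_rate_lag{int(lag)}", sub["t1_seen"].mean())
        seen1 = sub[sub["t1_seen"] == 1]
        add(subj, cond, "blink", f"t2_given_t1_lag{int(lag)}",
            seen1["t2_seen"].mean() if len(seen1) else np.nan)

    for (subj, cond), sub in tables.gonogo.groupby(["subject", "condition"]):
        add(subj, cond, "gonogo", "accuracy", sub["correct"].mean())
        add(subj, cond, "gonogo", "rt_ms", _median_rt(sub, rt_summary))

    for (subj, cond), sub in tables.stroop.groupby(["subject", "condition"]):
        add(subj, cond, "stroop", "accuracy", sub["correct"].mean())
        for congr, tag in ((1, "congruent"), (0, "incongruent")):
            add(subj, cond, "stroop", f"rt_ms_{tag}",
                _median_rt(sub[sub["congruent"] == congr], rt_summary))

    for (subj, cond, part), sub in tables.tmt.groupby(
            ["subject", "condition", "part"]):
        add(subj, cond, "tmt", f"time_s_part{part}", sub["time_s"].mean())
        add(subj, cond, "tmt", f"errors_part{part}", sub["errors"].mean())

    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# physical activity
# ---------------------------------------------------------------------------

_ACTIVITY_METRICS = ("steps", "distance_km", "resting_min", "active_min")


def summarize_activity(activity: pd.DataFrame) -> dict:
    """Group means with SEM per weekday and condition, plus paired
    active-vs-placebo contrasts per metric (on subject means)."""
    if activity.empty:
        raise ValueError("activity table is empty")
    summary = (activity.groupby(["condition", "weekday"])[list(_ACTIVITY_METRICS)]
               .agg(["mean", "sem"]))
    contrasts = {}
    per_subj = activity.groupby(["subject", "condition"])[
        list(_ACTIVITY_METRICS)].mean().reset_index()
    wide = per_subj.pivot(index="subject", columns="condition")
    for metric in _ACTIVITY_METRICS:
        a = wide[(metric, "active")].to_numpy()
        p = wide[(metric, "placebo")].to_numpy()
        ok = ~(np.isnan(a) | np.isnan(p))
        try:
            contrasts[metric] = paired_compare(a[ok], p[ok], name=f"activity_{metric}")
        except ValueError as exc:
            contrasts[metric] = TestResult(name=f"activity_{metric}",
                                           statistic=np.nan, p=np.nan,
                                           n=int(ok.sum()), degenerate=True,
                                           notes={"reason": str(exc)})
    return {"summary": summary, "contrasts": contrasts}


# ---------------------------------------------------------------------------
# dose arithmetic
# ---------------------------------------------------------------------------

def capsule_alkaloid_mass(concentrations: dict | None = None,
                          capsule_mass_g: float = 0.5) -> dict:
    """Alkaloid content of one capsule.

    Per-alkaloid mass (ug) = concentration (ug/g) x capsule mass (g).  The
    psilocybin-equivalent dose converts psilocin by the molecular-weight
    ratio 284.25/204.23 (psilocybin is the phosphorylated prodrug of
    psilocin); the raw sum of the two masses is reported alongside.
    """
    if concentrations is None:
        concentrations = DEFAULT_ALKALOID_CONCENTRATIONS
    if capsule_mass_g <= 0:
        raise ValueError("capsule mass must be positive")
    if any(v < 0 for v in concentrations.values()):
        raise ValueError("concentrations must be nonnegative")
    masses_ug = {k: v * capsule_mass_g for k, v in concentrations.items()}
    psilocybin = masses_ug.get("psilocybin", 0.0)
    psilocin = masses_ug.get("psilocin", 0.0)
    equivalent_ug = psilocybin + psilocin * (PSILOCYBIN_MW / PSILOCIN_MW)
    return {
        "masses_ug": masses_ug,
        "psilocybin_equivalent_mg": equivalent_ug / 1000.0,
        "psilocybin_plus_psilocin_mg": (psilocybin + psilocin) / 1000.0,
        "method": "molecular-weight ratio 284.25/204.23 applied to psilocin",
    }
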
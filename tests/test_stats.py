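"""Statistical kernels: exact rank tests, JZS Bayes factors, chi-squared,
scoring rules, and study-level analyses."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate

from psilodose import stats as st
from psilodose import synthetic as syn

from conftest import reported_unblinding_ledger


# ---------------------------------------------------------------------------
# enumeration oracles
# ---------------------------------------------------------------------------

def wilcoxon_exact_oracle(d):
    """Two-sided exact signed-rank p by enumerating all sign assignments."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = ranks[d > 0].sum()
    stats = [np.array(signs) @ ranks
             for signs in itertools.product([0, 1], repeat=len(d))]
    stats = np.array(stats)
    p_le = (stats <= w_obs).mean()
    p_ge = (stats >= w_obs).mean()
    return min(1.0, 2.0 * min(p_le, p_ge))


def mannwhitney_exact_oracle(x, y):
    """Two-sided exact Mann-Whitney p by enumerating all group labelings."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    nx = len(x)

    def u_of(idx):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        return ((xs[:, None] > ys[None, :]).sum()
                + 0.5 * (xs[:, None] == ys[None, :]).sum())

    u_obs = u_of(range(nx))
    us = np.array([u_of(c) for c in
                   itertools.combinations(range(len(pooled)), nx)])
    p_le = (us <= u_obs).mean()
    p_ge = (us >= u_obs).mean()
    return min(1.0, 2.0 * min(p_le, p_ge))


def jzs_oracle(t, n1, n2=None, r=math.sqrt(2) / 2.0):
    """High-precision quadrature of the JZS integral on (0, inf) without a
    change of variables (independent numerical route)."""
    if n2 is None:
        n_eff, df = float(n1), n1 - 1
    else:
        n_eff, df = n1 * n2 / (n1 + n2), n1 + n2 - 2

    def fun(g):
        a = 1.0 + n_eff * g * r * r
        return (a ** -0.5 * (1.0 + t * t / (a * df)) ** (-(df + 1) / 2.0)
                * (2.0 * math.pi) ** -0.5 * g ** -1.5
                * math.exp(-1.0 / (2.0 * g)))

    integral, _ = integrate.quad(fun, 0.0, np.inf, limit=500,
                                 epsabs=1e-13, epsrel=1e-12)
    return integral / (1.0 + t * t / df) ** (-(df + 1) / 2.0)


class TestPairedCompare:
    def test_exact_p_for_three_positive_differences(self):
        res = st.paired_compare([2.0, 3.0, 4.0], [1.0, 1.0, 1.0])
        assert res.p == pytest.approx(0.25)
        assert res.notes["p_method"] == "exact"

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 9))
            x = rng.standard_normal(n)
            y = rng.standard_normal(n)
            res = st.paired_compare(x, y)
            assert res.p == pytest.approx(wilcoxon_exact_oracle(x - y))

    def test_identical_samples_degenerate(self):
        res = st.paired_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.degenerate
        assert math.isnan(res.p)

    def test_power_at_one_sd_shift(self, rng):
        hits = 0
        for _ in range(60):
            x = rng.standard_normal(30) + 1.0
            y = rng.standard_normal(30)
            hits += st.paired_compare(x, y).p < 0.05
        assert hits / 60 > 0.9

    def test_bf10_attached(self, rng):
        res = st.paired_compare(rng.standard_normal(12) + 2.0,
                                rng.standard_normal(12))
        assert res.bf10 is not None and res.bf10 > 0


class TestUnpairedCompare:
    def test_exact_p_for_separated_triples(self):
        res = st.unpaired_compare([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p == pytest.approx(0.1)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(15):
            x = rng.standard_normal(int(rng.integers(3, 7)))
            y = rng.standard_normal(int(rng.integers(3, 7)))
            res = st.unpaired_compare(x, y)
            assert res.p == pytest.approx(mannwhitney_exact_oracle(x, y))

    def test_u_statistic_identity(self, rng):
        x = rng.standard_normal(7)
        y = rng.standard_normal(9)
        u_xy = st.unpaired_compare(x, y).statistic
        u_yx = st.unpaired_compare(y, x).statistic
        assert u_xy + u_yx == pytest.approx(len(x) * len(y))

    def test_identical_samples_p_one(self):
        res = st.unpaired_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p == pytest.approx(1.0)


class TestJZSBayesFactor:
    @pytest.mark.parametrize("t,n1,n2", [
        (0.0, 34, None), (1.0, 10, None), (2.5, 30, None), (-3.2, 16, None),
        (4.5, 25, None), (0.5, 8, None), (2.0, 15, 18), (-1.5, 12, 12),
        (3.7, 20, 25),
    ])
    def test_matches_independent_quadrature_to_4_digits(self, t, n1, n2):
        mine = st.jzs_bf10(t, n1, n2)
        ref = jzs_oracle(t, n1, n2)
        assert mine == pytest.approx(ref, rel=5e-5)

    def test_matches_pingouin(self):
        import pingouin as pg

        for t, n in [(0.0, 34), (2.5, 30), (5.0, 12), (-1.2, 20)]:
            assert st.jzs_bf10(t, n) == pytest.approx(
                float(pg.bayesfactor_ttest(t, n)), rel=1e-3)

    def test_null_t_favors_null(self):
        assert st.jzs_bf10(0.0, 34) < 1.0

    def test_monotone_in_abs_t(self):
        grid = [st.jzs_bf10(t, 20) for t in np.linspace(0, 6, 25)]
        assert all(b > a for a, b in zip(grid, grid[1:]))

    def test_evidence_categories(self):
        assert st.bf_category(50.0) == "very strong"
        assert st.bf_category(1.0) == "inconclusive"
        assert st.bf_category(0.5) == "inconclusive"
        assert st.bf_category(150.0) == "extreme"
        assert "null" in st.bf_category(0.01)

    def test_nonfinite_t_rejected(self):
        with pytest.raises(ValueError):
            st.jzs_bf10(float("nan"), 10)


class TestBonferroniAndChi2:
    def test_bonferroni(self):
        assert st.bonferroni_adjust(0.01, 4) == pytest.approx(0.04)
        assert st.bonferroni_adjust(0.5, 4) == 1.0
        assert st.bonferroni_adjust(0.2, 1) == pytest.approx(0.2)

    def test_chi2_diagonal_table(self):
        assert st.chi2_independence([[10, 0], [0, 10]],
                                    yates=False).statistic == pytest.approx(20.0)
        assert st.chi2_independence([[10, 0], [0, 10]],
                                    yates=True).statistic == pytest.approx(16.2)

    def test_chi2_independent_table(self):
        res = st.chi2_independence([[5, 5], [5, 5]], yates=False)
        assert res.statistic == 0.0
        assert res.p == pytest.approx(1.0)

    def test_chi2_matches_scipy(self, rng):
        from scipy.stats import chi2_contingency

        for _ in range(20):
            tab = rng.integers(1, 30, size=(2, 2))
            for yates in (True, False):
                mine = st.chi2_independence(tab, yates=yates)
                ref = chi2_contingency(tab, correction=yates)
                assert mine.statistic == pytest.approx(ref.statistic)
                assert mine.p == pytest.approx(ref.pvalue)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            st.chi2_independence([[0, 0], [5, 5]])


class TestUnblinding:
    def test_reported_pattern_gives_73_5_percent(self):
        report = st.unblinding_analysis(reported_unblinding_ledger())
        assert report["pct_correct_active"] == 73.5

    def test_all_correct(self):
        cfg = syn.StudyDesignConfig(n_subjects=10, p_correct_guess=1.0, seed=0)
        report = st.unblinding_analysis(syn.gen_study_ledger(cfg))
        assert report["pct_correct_active"] == 100.0
        assert report["pct_correct_placebo"] == 100.0

    def test_null_guesses_give_uniform_chi2_p(self):
        ps = []
        for seed in range(120):
            cfg = syn.StudyDesignConfig(n_subjects=34, p_correct_guess=0.5,
                                        seed=seed)
            rep = st.unblinding_analysis(syn.gen_study_ledger(cfg), yates=False)
            for wk in rep["weeks"].values():
                if wk["chi2"] is not None:
                    ps.append(wk["chi2"].p)
        ps = np.array(ps)
        # discrete test: check the rejection rate rather than full uniformity
        assert (ps < 0.05).mean() < 0.08


class TestScoring:
    def test_questionnaire_normalization(self):
        assert st.normalize_questionnaire(30, 60) == pytest.approx(5.0)
        assert st.normalize_questionnaire(0, 7) == 0.0
        assert st.normalize_questionnaire(60, 60) == 10.0
        with pytest.raises(ValueError):
            st.normalize_questionnaire(61, 60)

    def test_unique_response_among_100_scores_two(self):
        responses = {f"s{i}": ["shared"] for i in range(100)}
        responses["s0"] = ["shared", "rare_one"]
        df = st.score_divergent(responses).set_index("subject")
        # rare_one given by 1/100 subjects -> f = 0.01 -> 2 points
        assert df.loc["s0", "originality"] == 2

    def test_common_response_scores_zero(self):
        responses = {f"s{i}": ["everyone"] for i in range(10)}
        df = st.score_divergent(responses)
        assert (df["originality"] == 0).all()

    def test_disjoint_responses_normalize_to_two(self):
        responses = {f"s{i}": [f"w{i}_{k}" for k in range(4)]
                     for i in range(100)}
        df = st.score_divergent(responses)
        assert np.allclose(df["originality_per_fluency"], 2.0)
        assert (df["repetitions"] == 0).all()

    def test_within_subject_repetitions_counted(self):
        responses = {"a": ["x", "x", "y"], "b": ["z"]}
        df = st.score_divergent(responses).set_index("subject")
        assert df.loc["a", "repetitions"] == 1
        assert df.loc["a", "fluency"] == 3


class TestGammaFit:
    def test_recovers_known_mean(self, rng):
        durs = rng.gamma(2.0, 1.5, size=500)
        fit = st.fit_gamma_dominance(durs)
        assert fit.mean == pytest.approx(3.0, abs=0.2)
        assert not fit.fallback

    def test_fitted_mean_close_to_sample_mean(self, rng):
        durs = rng.gamma(3.0, 0.8, size=400)
        fit = st.fit_gamma_dominance(durs)
        assert fit.mean == pytest.approx(durs.mean(), rel=0.05)

    def test_constant_sample_falls_back(self):
        fit = st.fit_gamma_dominance(np.full(20, 2.5))
        assert fit.fallback
        assert fit.mean == pytest.approx(2.5)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            st.fit_gamma_dominance(np.array([1.0] * 9 + [-0.1]))


@pytest.fixture(scope="module")
def battery():
    cfg = syn.StudyDesignConfig(n_subjects=12, seed=3)
    ledger = syn.gen_study_ledger(cfg)
    return syn.gen_behavioral_battery(ledger, seed=3), ledger


class TestTaskAndActivitySummaries:
    def test_blink_dip_at_300ms_only(self, battery):
        bt, _ = battery
        metrics = st.summarize_tasks(bt)
        t2 = (metrics[metrics["metric"].str.startswith("t2_given_t1")]
              .groupby("metric")["value"].mean())
        dip = t2["t2_given_t1_lag300"]
        others = t2.drop("t2_given_t1_lag300")
        assert dip < others.min() - 0.15

    def test_median_rt(self):
        df = pd.DataFrame({"rt_ms": [200.0, 400.0, 600.0]})
        assert st._median_rt(df, "median") == 400.0

    def test_all_correct_fixture_gives_unit_accuracy(self, battery):
        bt, _ = battery
        bt.gonogo["correct"] = 1
        metrics = st.summarize_tasks(bt)
        acc = metrics[(metrics["task"] == "gonogo")
                      & (metrics["metric"] == "accuracy")]["value"]
        assert (acc == 1.0).all()

    def test_activity_summary_sem_and_dip(self, battery):
        _, ledger = battery
        act = syn.gen_activity_data(ledger, seed=3, dip_factor=0.7)
        rep = st.summarize_activity(act)
        steps = rep["summary"]["steps"]
        # SEM = SD/sqrt(n) against direct computation for one cell
        sub = act[(act["condition"] == "active") & (act["weekday"] == "Mon")]
        direct = sub["steps"].std(ddof=1) / np.sqrt(len(sub))
        assert steps.loc[("active", "Mon"), "sem"] == pytest.approx(direct)
        wed_means = steps.loc[("active",), "mean"]
        assert wed_means.idxmin() == "Wed"

    def test_identical_conditions_degenerate_contrast(self, battery):
        _, ledger = battery
        act = syn.gen_activity_data(ledger, seed=3, steps_sd=0.0,
                                    resting_sd=0.0, active_sd=0.0,
                                    dip_factor=1.0)
        rep = st.summarize_activity(act)
        assert rep["contrasts"]["steps"].degenerate


class TestVASAndBlinding:
    def test_totals_and_missing_items(self, ledger, design):
        vas = syn.gen_vas_records(ledger, design)
        scored = st.vas_scores(vas)
        assert np.allclose(scored["total"],
                           scored[list(syn.VAS_ITEMS)].sum(axis=1))
        broken = vas.drop(columns=[syn.VAS_ITEMS[0]])
        with pytest.raises(ValueError, match=syn.VAS_ITEMS[0]):
            st.vas_scores(broken)

    def test_trivial_totals(self):
        row = {"subject": 1, "week": 1, "condition": "active", "day": "Wed"}
        zeros = pd.DataFrame([{**row, **{i: 0.0 for i in syn.VAS_ITEMS}}])
        tens = pd.DataFrame([{**row, **{i: 10.0 for i in syn.VAS_ITEMS}}])
        assert st.vas_scores(zeros)["total"].iloc[0] == 0.0
        assert st.vas_scores(tens)["total"].iloc[0] == 210.0

    def test_split_partition(self, ledger, design):
        records = st.vas_scores(syn.gen_vas_records(ledger, design))
        unblinded, blinded = st.split_by_blinding(ledger, records)
        assert len(unblinded) + len(blinded) == len(records)
        merged = records.merge(ledger[["subject", "week", "correct"]],
                               on=["subject", "week"])
        assert len(unblinded) == int(merged["correct"].sum())

    def test_split_sizes_near_half_at_p_half(self):
        sizes = []
        for seed in range(40):
            cfg = syn.StudyDesignConfig(n_subjects=34, p_correct_guess=0.5,
                                        seed=seed)
            led = syn.gen_study_ledger(cfg)
            rec = st.vas_scores(syn.gen_vas_records(led, cfg))
            u, b = st.split_by_blinding(led, rec)
            sizes.append(len(u) / len(rec))
        assert np.mean(sizes) == pytest.approx(0.5, abs=0.05)

    def test_record_without_ledger_row_rejected(self, ledger, design):
        records = st.vas_scores(syn.gen_vas_records(ledger, design))
        orphan = records.copy()
        orphan.loc[orphan.index[0], "subject"] = 9999
        with pytest.raises(KeyError):
            st.split_by_blinding(ledger, orphan)

    def test_subject_level_split_counts(self):
        cfg = syn.StudyDesignConfig(n_subjects=34, p_correct_guess=1.0, seed=0)
        led = syn.gen_study_ledger(cfg)
        unblinded, blinded = st.split_subjects_by_unblinding(led)
        assert len(unblinded) == 34 and not blinded


class TestDoseArithmetic:
    def test_capsule_masses(self):
        out = st.capsule_alkaloid_mass()
        assert out["masses_ug"]["psilocybin"] == pytest.approx(320.1)
        assert out["psilocybin_equivalent_mg"] == pytest.approx(0.98, abs=0.01)
        assert out["psilocybin_plus_psilocin_mg"] == pytest.approx(0.795,
                                                                   abs=0.005)

    def test_zero_concentrations(self):
        out = st.capsule_alkaloid_mass({"psilocybin": 0.0, "psilocin": 0.0})
        assert out["psilocybin_equivalent_mg"] == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            st.capsule_alkaloid_mass({"psilocybin": -1.0})
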
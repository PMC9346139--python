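import numpy as np
import pandas as pd
import pytest

from psilodose import synthetic as syn


@pytest.fixture(scope="session")
def small_eeg_config():
    return syn.SyntheticEEGConfig(n_channels=4, duration=20.0, seed=123)


@pytest.fixture(scope="session")
def design():
    return syn.StudyDesignConfig(seed=7)


@pytest.fixture(scope="session")
def ledger(design):
    return syn.gen_study_ledger(design)


def reported_unblinding_ledger() -> pd.DataFrame:
    """Deterministic ledger reproducing the study's reported guess pattern:
    34 subjects, active week guessed correctly by exactly 25."""
    rows = []
    for subj in range(1, 35):
        active_correct = subj <= 25
        placebo_correct = subj <= 24  # ~70% on the placebo weeks
        for week, cond, correct in ((1, "active", active_correct),
                                    (2, "placebo", placebo_correct)):
            guess = cond if correct else ("placebo" if cond == "active" else "active")
            rows.append({"subject": subj, "week": week, "condition": cond,
                         "guess": guess, "correct": correct})
    return pd.DataFrame(rows)


def lz76_oracle(s) -> int:
    """Brute-force exhaustive-history LZ76 word count via naive substring
    search: a phrase extends while it can be copied from the history that
    precedes its final symbol."""
    s = "".join(str(int(x)) for x in s)
    n = len(s)
    c = 0
    p = 0
    while p < n:
        k = 1
        while p + k <= n and s[p:p + k] in s[:p + k - 1]:
            k += 1
        c += 1
        p += min(k, n - p)
    return c


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
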
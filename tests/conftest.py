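import warnings

import numpy as np
import pandas as pd
import pytest

import btract as bt
from btract.panel import EMAPanel, StudyDesign


def make_panel(rows, items=("A", "B", "C"), prompts_per_day=8, days=6):
    """Build a tiny panel from (subject, day, prompt, dict-of-scores) tuples."""
    data = []
    for sid, day, prompt, scores in rows:
        row = {"subject_id": sid, "day": day, "prompt": prompt}
        for it in items:
            row[it] = scores.get(it, np.nan)
        data.append(row)
    df = pd.DataFrame(data, columns=["subject_id", "day", "prompt", *items])
    return EMAPanel(df, tuple(items), StudyDesign(prompts_per_day, days)).sort()


@pytest.fixture(scope="session")
def null_cohort():
    """Small cohort with zero couplings: every edge estimate is pure noise."""
    spec = bt.GenerativeSpec(
        n_subjects=20,
        item_names=bt.EMA_ITEMS[:6],
        compliance=1.0,
        intercept_sd=0.5,
        seed=11,
    )
    return bt.generate_cohort(spec)


@pytest.fixture(scope="session")
def coupled_cohort():
    """Cohort with one strong cross edge and one strong lagged edge."""
    k = 5
    cross = np.zeros((k, k))
    cross[1, 2] = cross[2, 1] = 0.6
    lag = np.zeros((k, k))
    lag[0, 3] = 0.5
    spec = bt.GenerativeSpec(
        n_subjects=40,
        item_names=bt.EMA_ITEMS[:k],
        cross_coupling=cross,
        lag_coupling=lag,
        compliance=1.0,
        intercept_sd=0.6,
        seed=7,
    )
    return bt.generate_cohort(spec)


@pytest.fixture(scope="session")
def coupled_networks(coupled_cohort):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return bt.build_networks(coupled_cohort.panel)
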
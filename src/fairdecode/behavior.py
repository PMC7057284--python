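"""Behavioral statistics for the mixed ultimatum/dictator paradigm.

Per subject, the mean offer in each (game x opponent) cell and the UG-DG
offer difference -- the behavioral index of strategic (selfish) vs prosocial
motivation.  Group-level checks: a pooled two-sample t-test comparing the
offer gap between the two cohorts, and an OLS regression predicting
trial-level DG offers from opponent type, the offer gap and their
interaction (a negative interaction means the social premium on DG offers is
largest for prosocial players).
"""
from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .glm import GAMES, OPPONENTS, validate_events

__all__ = [
    "offer_differences",
    "cohort_ttest",
    "dg_regression",
]

CELLS = [(g, o) for g in GAMES for o in OPPONENTS]


def offer_differences(
    events_by_subject: dict[str, pd.DataFrame],
    cohorts: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-subject mean offers by cell and UG-DG differences per opponent.

    ``events_by_subject`` maps subject id to its event table.  Every subject
    must populate all four (game, opponent) cells.  Returns a BehaviorTable
    with columns ``subject_id, cohort, mean_<game>_<opponent> x4,
    ug_dg_diff_human, ug_dg_diff_computer``.
    """
    rows = []
    for sid, events in events_by_subject.items():
        ev = validate_events(events)
        cell_means = {}
        for game, opp in CELLS:
            sel = ev[(ev["game"] == game) & (ev["opponent"] == opp)]
            if sel.empty:
                raise ValueError(f"subject {sid}: no trials in cell ({game}, {opp})")
            cell_means[f"mean_{game}_{opp}"] = float(sel["offer"].mean())
        row = {"subject_id": sid,
               "cohort": int(cohorts[sid]) if cohorts else 1, **cell_means}
        row["ug_dg_diff_human"] = row["mean_UG_human"] - row["mean_DG_human"]
        row["ug_dg_diff_computer"] = row["mean_UG_computer"] - row["mean_DG_computer"]
        rows.append(row)
    return pd.DataFrame(rows)


def cohort_ttest(diffs: np.ndarray, cohort: np.ndarray) -> tuple[float, int, float]:
    """Pooled-variance two-sample t-test of the offer gap between cohorts.

    Groups follow the sorted order of the cohort labels (cohort 1 minus
    cohort 2).  Returns (t, df, two-sided p) with df = n1 + n2 - 2.
    """
    diffs = np.asarray(diffs, dtype=float)
    cohort = np.asarray(cohort)
    levels = np.unique(cohort)
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 cohorts, got {len(levels)}")
    a = diffs[cohort == levels[0]]
    b = diffs[cohort == levels[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each cohort needs at least 2 subjects")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), len(a) + len(b) - 2, float(p)


def dg_regression(
    dg_trials: pd.DataFrame,
    offer_column: str = "offer",
    human_column: str = "is_human",
    diff_column: str = "ug_dg_diff",
    unit: str = "trial",
) -> pd.DataFrame:
    """OLS of DG offers on opponent type, offer gap and their interaction.

    ``dg_trials`` is a long table of dictator-game offers with a 0/1 human
    dummy and the subject's mean UG-DG offer difference repeated per row.
    ``unit='subject'`` first averages offers within subject x opponent.
    Returns a coefficient table (coef, se, t, p) for
    [intercept, human, diff, human x diff] with R^2 attached as
    ``.attrs['r_squared']``.
    """
    df = dg_trials.copy()
    if unit not in ("trial", "subject"):
        raise ValueError(f"unknown unit {unit!r}")
    if unit == "subject":
        if "subject_id" not in df.columns:
            raise ValueError("subject-level regression needs a subject_id column")
        df = (df.groupby(["subject_id", human_column], as_index=False)
                .agg({offer_column: "mean", diff_column: "first"}))
    human = df[human_column].to_numpy(dtype=float)
    diff = df[diff_column].to_numpy(dtype=float)
    if len(np.unique(human)) < 2:
        raise ValueError("both opponent levels must be present")
    if np.ptp(diff) == 0:
        raise ValueError("offer difference must vary across subjects")
    x = np.column_stack([human, diff, human * diff])
    x = sm.add_constant(x)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("collinear design: opponent dummy, offer difference "
                         "and interaction are linearly dependent")
    fit = sm.OLS(df[offer_column].to_numpy(dtype=float), x).fit()
    table = pd.DataFrame(
        {"coef": fit.params, "se": fit.bse, "t": fit.tvalues, "p": fit.pvalues},
        index=["intercept", "human", "diff", "human_x_diff"])
    table.attrs["r_squared"] = float(fit.rsquared)
    table.attrs["f_statistic"] = float(fit.fvalue)
    table.attrs["df_resid"] = float(fit.df_resid)
    return table
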
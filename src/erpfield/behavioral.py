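"""Behavioral ratings: rescaling, condition summaries, categorization.

Valence/arousal scores are rescaled per participant and measure so that zero
corresponds to that participant's mean rating across all three context
conditions; a positive condition mean then reads directly as "above the
participant's overall level".  Summaries report the mean and standard error
of participant-level condition means.  The explicit-categorization task is
summarized as the percentage of answers per emotion category and condition.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORIES",
    "rescale_scores",
    "condition_summary",
    "categorization_percentages",
]

CATEGORIES = ("Happiness", "Sadness", "Fear", "Anger", "Disgust", "Surprise", "Other")


def rescale_scores(ratings: pd.DataFrame, *, weighted: bool = True) -> pd.DataFrame:
    """Center scores on each participant x measure grand mean.

    ``weighted=True`` (default) uses the trial-weighted grand mean over all
    trials of the three conditions; with balanced designs this equals the
    unweighted mean of condition means (``weighted=False``).  Requires every
    participant to have trials in all conditions for each measure.
    """
    req = {"participant", "condition", "measure", "score"}
    if not req <= set(ratings.columns):
        raise ValueError(f"ratings table needs columns {sorted(req)}")
    conds = set(ratings["condition"].unique())
    for (pid, meas), grp in ratings.groupby(["participant", "measure"]):
        missing = conds - set(grp["condition"].unique())
        if missing:
            raise ValueError(f"participant {pid} missing conditions {sorted(missing)} for {meas}")
    out = ratings.copy()
    if weighted:
        grand = ratings.groupby(["participant", "measure"])["score"].transform("mean")
    else:
        cond_means = (ratings.groupby(["participant", "measure", "condition"])["score"]
                      .mean().groupby(["participant", "measure"]).mean())
        grand = ratings.set_index(["participant", "measure"]).index.map(cond_means)
        grand = pd.Series(np.asarray(grand, dtype=float), index=ratings.index)
    out["score"] = ratings["score"] - grand
    return out


def condition_summary(rescaled: pd.DataFrame) -> pd.DataFrame:
    """Mean and SE per condition x measure over participant-level means.

    SE is the standard deviation of participant condition means divided by
    sqrt(n participants).
    """
    per_part = (rescaled.groupby(["condition", "measure", "participant"])["score"]
                .mean().reset_index())
    n_part = per_part.groupby(["condition", "measure"])["participant"].nunique()
    if (n_part < 2).any():
        raise ValueError("need at least 2 participants")

    def _se(x):
        return float(np.std(x, ddof=1) / np.sqrt(len(x)))

    out = (per_part.groupby(["condition", "measure"])["score"]
           .agg(mean="mean", se=_se).reset_index())
    return out


def categorization_percentages(answers: pd.DataFrame) -> pd.DataFrame:
    """Percentage of answers per emotion category (rows) and condition (columns).

    ``answers`` needs columns ``condition`` and ``category``; every column
    sums to 100.
    """
    req = {"condition", "category"}
    if not req <= set(answers.columns):
        raise ValueError("answers table needs columns 'condition' and 'category'")
    unknown = set(answers["category"].unique()) - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown categories: {sorted(unknown)}")
    counts = pd.crosstab(answers["category"], answers["condition"])
    counts = counts.reindex(index=list(CATEGORIES), fill_value=0)
    return 100.0 * counts / counts.sum(axis=0)
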
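"""Published reference summaries used in worked examples and consistency tests.

These are descriptive statistics from a large North American Angus field
dataset of chute-side temperament scores: per-score record counts after
phenotypic quality control for yearling temperament (YT, one record per
animal) and cow-at-weaning temperament (CT, repeated records), and the
per-age-group score percentages.  The raw records themselves are proprietary;
only these printed summaries are public, and the package uses them as fixed
inputs for arithmetic checks (percentages, means) and as targets the
synthetic generator's defaults are calibrated against.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["yt_score_counts", "ct_score_counts", "age_group_score_percentages",
           "score_percentages", "mean_score_from_percentages"]


def yt_score_counts() -> pd.Series:
    """Yearling-temperament animals per raw score category (1..6)."""
    return pd.Series([188805, 63189, 14985, 1928, 256, 85],
                     index=pd.RangeIndex(1, 7, name="score"), name="n")


def ct_score_counts() -> pd.Series:
    """Cow-at-weaning temperament records per raw score category (1..6)."""
    return pd.Series([82739, 56394, 12925, 1325, 452, 63],
                     index=pd.RangeIndex(1, 7, name="score"), name="n")


def age_group_score_percentages() -> pd.DataFrame:
    """Score percentages per age group (youngest "<2" through ">10"),
    with record counts and mean ages in days."""
    labels = ["<2", "3", "4", "5", "6", "7", "8", "9", "10", ">10"]
    n = [269248, 47839, 33579, 23435, 16817, 11696, 8275, 5223, 3378, 3656]
    age = [375, 760, 1317, 1682, 2048, 2414, 2778, 3144, 3511, 4128]
    pct = np.array([
        [70.12, 23.47, 5.57, 0.72, 0.10, 0.03],
        [56.00, 35.53, 7.49, 0.73, 0.22, 0.03],
        [54.91, 35.83, 8.17, 0.80, 0.24, 0.05],
        [53.71, 36.48, 8.60, 0.85, 0.32, 0.04],
        [52.63, 36.84, 9.18, 0.95, 0.35, 0.05],
        [51.84, 37.59, 8.90, 1.15, 0.46, 0.07],
        [50.10, 39.70, 8.65, 1.11, 0.37, 0.06],
        [49.21, 39.71, 9.78, 1.00, 0.31, 0.00],
        [47.51, 39.93, 10.89, 1.01, 0.56, 0.09],
        [46.17, 41.52, 10.94, 1.04, 0.33, 0.00],
    ])
    df = pd.DataFrame(pct, columns=[f"pct_{s}" for s in range(1, 7)])
    df.insert(0, "group", labels)
    df.insert(1, "n", n)
    df.insert(2, "mean_age_days", age)
    return df


def score_percentages(counts: pd.Series, decimals: int = 2) -> pd.Series:
    """Percentage of records per score category, rounded."""
    return (100.0 * counts / counts.sum()).round(decimals)


def mean_score_from_percentages(pct, decimals: int = 2) -> float:
    """Mean score implied by per-score percentages."""
    pct = np.asarray(pct, dtype=float)
    scores = np.arange(1, pct.size + 1)
    return round(float((scores * pct).sum() / pct.sum()), decimals)
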
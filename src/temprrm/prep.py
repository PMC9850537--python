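"""Editing rules for longitudinal ordinal temperament records.

The raw chute-side score runs 1 (docile) to 6 (very aggressive); scores 4-6
are collapsed into one category before analysis because of their low
incidence.  Contemporary groups must keep at least three records and at least
two distinct scores; repeated records on the same cow must be at least 268
days apart (no cow weans two calves within a shorter interval).  Records are
binned into nine adult age groups, labelled "3".."10" and ">10" years.

All filters log every dropped row with a reason code and are idempotent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["AgeGroupScheme", "collapse_scores", "filter_contemporary_groups",
           "enforce_min_interval", "assign_age_groups", "summarize_scores",
           "prepare", "DropLog"]

#: Mean ages in days of the nine adult age groups (3 y ... >10 y).
AGE_GROUP_MEANS = (760.0, 1317.0, 1682.0, 2048.0, 2414.0, 2778.0, 3144.0,
                   3511.0, 4128.0)
AGE_GROUP_LABELS = ("3", "4", "5", "6", "7", "8", "9", "10", ">10")


def _default_boundaries() -> tuple:
    """Half-open bin edges at midpoints between consecutive group mean ages;
    the last bin is unbounded above."""
    means = np.asarray(AGE_GROUP_MEANS)
    inner = (means[:-1] + means[1:]) / 2.0
    return tuple([means[0], *inner])


@dataclass(frozen=True)
class AgeGroupScheme:
    """Nine age groups defined by strictly increasing day cutpoints.

    ``boundaries`` has one entry per group: the lower edge of each half-open
    bin [lo, next_lo); the final group extends to infinity.
    """

    boundaries: tuple = field(default_factory=_default_boundaries)
    labels: tuple = AGE_GROUP_LABELS

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        if np.any(np.diff(b) <= 0):
            raise ValueError("boundaries must be strictly increasing")
        if len(self.boundaries) != len(self.labels):
            raise ValueError(f"scheme must define {len(self.labels)} groups")


class DropLog:
    """Accumulates (row index, reason) pairs across prep steps."""

    def __init__(self):
        self.records: list = []

    def add(self, index, reason: str) -> None:
        self.records.extend((int(i), reason) for i in index)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records, columns=["row", "reason"])


def collapse_scores(t: pd.DataFrame) -> pd.DataFrame:
    """Map raw scores 4, 5, 6 onto category 4; 1-3 unchanged."""
    scores = t["score"]
    if scores.min() < 1 or scores.max() > 6:
        bad = t.loc[(scores < 1) | (scores > 6)].index.tolist()
        raise ValueError(f"scores outside 1..6 at rows {bad[:10]}")
    out = t.copy()
    out["score"] = scores.clip(upper=4)
    return out


def filter_contemporary_groups(t: pd.DataFrame, min_records: int = 3,
                               min_distinct: int = 2,
                               log: DropLog | None = None) -> pd.DataFrame:
    """Drop every contemporary group with fewer than ``min_records`` records
    or fewer than ``min_distinct`` distinct scores, re-checking to a fixed
    point."""
    out = t
    while True:
        g = out.groupby("cg")["score"]
        ok = (g.transform("size") >= min_records) & \
             (g.transform("nunique") >= min_distinct)
        if ok.all():
            break
        if log is not None:
            log.add(out.index[~ok], "cg_filter")
        out = out.loc[ok]
    if out.empty and not t.empty:
        warnings.warn("contemporary-group filter removed every record",
                      stacklevel=2)
    return out


def enforce_min_interval(t: pd.DataFrame, min_days: float = 268,
                         log: DropLog | None = None) -> pd.DataFrame:
    """Greedy forward scan per animal: drop any record closer than
    ``min_days`` to the last retained record (the earlier record wins).
    Duplicate (animal, age) rows keep the first occurrence, with a warning."""
    t = t.sort_values(["animal", "age_days"], kind="stable")
    dup = t.duplicated(subset=["animal", "age_days"])
    if dup.any():
        warnings.warn(f"{int(dup.sum())} duplicate (animal, age) records; "
                      "keeping first", stacklevel=2)
        if log is not None:
            log.add(t.index[dup], "duplicate_age")
        t = t.loc[~dup]
    keep = np.ones(len(t), dtype=bool)
    animals = t["animal"].to_numpy()
    ages = t["age_days"].to_numpy(dtype=float)
    last_animal, last_age = None, -np.inf
    for i in range(len(t)):
        if animals[i] != last_animal:
            last_animal, last_age = animals[i], ages[i]
            continue
        if ages[i] - last_age < min_days:
            keep[i] = False
        else:
            last_age = ages[i]
    if log is not None:
        log.add(t.index[~keep], "min_interval")
    return t.loc[keep]


def assign_age_groups(t: pd.DataFrame,
                      scheme: AgeGroupScheme | None = None) -> pd.DataFrame:
    """Label each record with its age group (half-open bins [lo, hi))."""
    scheme = scheme or AgeGroupScheme()
    edges = np.asarray(scheme.boundaries, dtype=float)
    ages = t["age_days"].to_numpy(dtype=float)
    if np.any(ages < edges[0]):
        bad = t.index[ages < edges[0]].tolist()
        raise ValueError(f"ages below first boundary at rows {bad[:10]}")
    idx = np.searchsorted(edges, ages, side="right") - 1
    out = t.copy()
    out["age_group"] = [scheme.labels[i] for i in idx]
    return out


def summarize_scores(t: pd.DataFrame, by: str | None = None) -> pd.DataFrame:
    """Per-group score distribution: count, per-score counts and percentages
    (2 d.p.), and the mean and SD of the score."""
    if t.empty:
        raise ValueError("cannot summarize an empty table")
    groups = t.groupby(by) if by else [("all", t)]
    rows = []
    for key, g in groups:
        scores = g["score"]
        row = {"group": key, "n": len(g)}
        for s in sorted(t["score"].unique()):
            c = int((scores == s).sum())
            row[f"n_{s}"] = c
            row[f"pct_{s}"] = round(100.0 * c / len(g), 2)
        row["mean"] = round(float(scores.mean()), 2)
        row["sd"] = round(float(scores.std(ddof=1)), 2) if len(g) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def prepare(t: pd.DataFrame, scheme: AgeGroupScheme | None = None,
            min_interval_days: float = 268):
    """Full editing pipeline: collapse scores, enforce the minimum interval,
    filter contemporary groups, assign age groups.  Returns (table, DropLog).

    The interval rule runs before the CG filter so that group counts reflect
    the final record set.
    """
    log = DropLog()
    out = collapse_scores(t)
    out = enforce_min_interval(out, min_interval_days, log=log)
    out = filter_contemporary_groups(out, log=log)
    if not out.empty:
        out = assign_age_groups(out, scheme)
    return out, log
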
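"""Kaplan-Meier syncope-free survival and the two-group log-rank test.

Time is measured in years since each person's follow-up start (the study
start or birth, whichever is later); right censoring occurs at death,
emigration or the administrative end of follow-up.  Groups are defined at
baseline: a person belongs to the "relative affected" curve when at least one
relative of the given class was diagnosed during the study window.  At tied
year-resolution times, events are taken to precede censorings (the standard
product-limit convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test


class SurvivalError(ValueError):
    pass


@dataclass
class SurvivalCurve:
    """Product-limit estimate for one group."""

    group: str
    times: np.ndarray          # years since follow-up start
    survival: np.ndarray       # S(t), non-increasing from 1.0
    at_risk: np.ndarray
    events: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"group": self.group, "time": self.times,
                             "survival": self.survival,
                             "at_risk": self.at_risk, "events": self.events})


@dataclass(frozen=True)
class LogRankResult:
    chi_square: float
    p_value: float
    df: int = 1


def km_curve(durations: Sequence[float], events: Sequence[bool],
             group: str = "") -> SurvivalCurve:
    """Kaplan-Meier curve from follow-up durations and event flags."""
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=bool)
    if len(durations) == 0:
        raise SurvivalError(f"empty group {group!r}")
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=events)
    tab = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"].reindex(tab.index).to_numpy()
    return SurvivalCurve(
        group=group,
        times=tab.index.to_numpy(dtype=float),
        survival=surv,
        at_risk=tab["at_risk"].to_numpy(),
        events=tab["observed"].to_numpy(),
    )


def km_by_group(follow: pd.DataFrame, groups: pd.Series) -> Dict[str, SurvivalCurve]:
    """One curve per group label over follow-up rows (duration =
    person_years, event flag from the follow-up table)."""
    out: Dict[str, SurvivalCurve] = {}
    f = follow[~follow["excluded"]]
    g = groups.reindex(f.index)
    for label in pd.unique(g.dropna()):
        sub = f[g == label]
        out[str(label)] = km_curve(sub["person_years"], sub["event"], str(label))
    return out


def log_rank(durations_a: Sequence[float], events_a: Sequence[bool],
             durations_b: Sequence[float], events_b: Sequence[bool]
             ) -> LogRankResult:
    """Standard two-group log-rank test (chi-square with 1 df)."""
    da, db = np.asarray(durations_a, float), np.asarray(durations_b, float)
    if len(da) == 0 or len(db) == 0:
        raise SurvivalError("both groups must be non-empty")
    if da.sum() == 0 or db.sum() == 0:
        raise SurvivalError("a group has zero at-risk time")
    res = logrank_test(da, db, event_observed_A=np.asarray(events_a, bool),
                       event_observed_B=np.asarray(events_b, bool))
    return LogRankResult(chi_square=float(res.test_statistic),
                         p_value=float(res.p_value))


def familial_survival(follow: pd.DataFrame, pairs: pd.DataFrame,
                      relation: str) -> Tuple[Dict[str, SurvivalCurve], LogRankResult]:
    """Curves and log-rank test for one relationship class, grouped by
    baseline relative history."""
    rows = pairs[pairs["relation"] == relation]
    if not len(rows):
        raise SurvivalError(f"no pairs for relation {relation!r}")
    aff = follow["event"]
    rel_aff = aff.reindex(rows["relative_id"]).to_numpy(dtype=bool)
    exposed = (pd.Series(rel_aff, index=rows["index_id"].to_numpy())
               .groupby(level=0).any())
    members = follow.reindex(exposed.index)
    members = members[~members["excluded"]]
    exposed = exposed.reindex(members.index)
    labels = exposed.map({True: "relative affected", False: "relative unaffected"})
    curves = km_by_group(members, labels)
    ga = members[exposed]
    gb = members[~exposed]
    lr = log_rank(ga["person_years"], ga["event"], gb["person_years"], gb["event"])
    return curves, lr


def plot_curves(curves: Dict[str, SurvivalCurve], path, title: str = "") -> None:
    """Optional step-plot of curves (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for label, c in curves.items():
        ax.step(c.times, c.survival, where="post", label=label)
    ax.set_xlabel("years since start of follow-up")
    ax.set_ylabel("syncope-free survival")
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
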
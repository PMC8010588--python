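"""Report tables: cohort descriptives and the familial-risk layout.

These helpers turn counts and fitted results into the delimited-text tables
the pipeline writes: a cohort-characteristics table (counts and percentages
affected, by relationship dataset and sex, with onset-age descriptives) and a
familial-risk table (person-years, cases/persons at risk, incidence rates,
IRR, crude and adjusted ORs, tetrachoric correlation per relationship).
"""

from __future__ import annotations

from typing import Dict, Iterable, Optional

import numpy as np
import pandas as pd

from .association import FamilialAggregationResults
from .registry import Registry


def proportion(count: float, total: float, percent: bool = True,
               ndigits: Optional[int] = 2) -> float:
    """Share of a count in a total, as a (rounded) percentage by default."""
    if total <= 0:
        raise ValueError("total must be positive")
    p = count / total
    if percent:
        p *= 100.0
    return round(p, ndigits) if ndigits is not None else p


def cohort_table(registry: Registry, follow: pd.DataFrame,
                 datasets: Dict[str, Iterable[str]]) -> pd.DataFrame:
    """Cohort characteristics per dataset ('all' plus each relationship set).

    ``datasets`` maps a dataset label to the person ids it contains.  Emits
    counts, affected counts and percentages overall and by sex, plus
    median/IQR age at onset (descriptive only).
    """
    p = registry.persons.set_index("person_id")
    rows = []
    for label, ids in datasets.items():
        ids = pd.Index(pd.unique(pd.Series(list(ids))))
        sub = p.reindex(ids)
        f = follow.reindex(ids)
        included = ~f["excluded"]
        sub, f = sub[included], f[included]
        aff = f["event"].astype(bool)
        onset_age = (f.loc[aff, "event_year"] - sub.loc[aff, "birth_year"]).astype(float)
        row = {
            "dataset": label,
            "n": int(len(sub)),
            "n_affected": int(aff.sum()),
            "pct_affected": proportion(aff.sum(), max(len(sub), 1)),
        }
        for sex in ("male", "female"):
            m = sub["sex"] == sex
            row[f"n_{sex}"] = int(m.sum())
            row[f"n_{sex}_affected"] = int((aff & m).sum())
            row[f"pct_{sex}_affected"] = (
                proportion((aff & m).sum(), m.sum()) if m.sum() else np.nan)
        row["pct_affected_female_share"] = (
            proportion((aff & (sub["sex"] == "female")).sum(), aff.sum())
            if aff.sum() else np.nan)
        row["onset_age_median"] = float(onset_age.median()) if len(onset_age) else np.nan
        row["onset_age_q1"] = float(onset_age.quantile(0.25)) if len(onset_age) else np.nan
        row["onset_age_q3"] = float(onset_age.quantile(0.75)) if len(onset_age) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def familial_risk_table(results: FamilialAggregationResults) -> pd.DataFrame:
    """Tidy familial-risk layout: one row per relationship x exposure level
    with person-years, cases/at-risk, rate, plus per-relationship IRR, ORs
    and tetrachoric correlation (display rounding: 2 decimals)."""
    out = []
    for rel, (exp_s, unexp_s) in results.exposure.items():
        for label, s in (("unaffected", unexp_s), ("affected", exp_s)):
            row = {
                "relation": rel, "relative": label,
                "person_years": s.person_years,
                "cases": s.cases, "persons_at_risk": s.persons_at_risk,
            }
            try:
                r = results.get("incidence_rate", rel, f"relative_{label}")
                row.update(rate=round(r.value, 2), rate_ci_low=round(r.ci_low, 2),
                           rate_ci_high=round(r.ci_high, 2))
            except KeyError:
                pass
            if label == "affected":
                for m, key in (("IRR", "irr"), ("OR_crude", "or_crude"),
                               ("OR_adjusted", "or_adjusted")):
                    try:
                        e = results.get(m, rel)
                        row[key] = round(e.value, 2)
                        row[f"{key}_ci_low"] = round(e.ci_low, 2)
                        row[f"{key}_ci_high"] = round(e.ci_high, 2)
                    except KeyError:
                        pass
                try:
                    t = results.get("tetrachoric", rel)
                    row["tetrachoric"] = round(t.value, 2)
                    row["tetrachoric_se"] = round(t.se, 2)
                except KeyError:
                    pass
            out.append(row)
    return pd.DataFrame(out)
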
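"""Relative-pair extraction, exclusion rules and double-entry tabulation.

Four relationship datasets are built from parent links: twins (shared twin
group), full siblings (same mother and father, twins removed), half-siblings
(exactly one shared parent) and first cousins (a parent of each is a full
sibling of a parent of the other).  Every dataset is double-entered: each
unordered pair appears twice, once with each member as the index person, so
each person's outcome can be regressed on each relative's status.

Both biological parents must be known for a person to contribute pairs.
A person may appear in more than one relationship dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .registry import Registry

#: Genetic resemblance attached to emitted pairs. The twin value is the
#: MZ/DZ-mixture mean (see the zygosity module); the rest are exact.
RESEMBLANCE: Dict[str, float] = {
    "twin": 0.66,
    "full_sibling": 0.5,
    "half_sibling": 0.25,
    "cousin": 0.125,
}

RELATIONS = ("twin", "full_sibling", "half_sibling", "cousin")

PAIR_COLUMNS = ["index_id", "relative_id", "relation", "resemblance"]


class PairError(ValueError):
    pass


def _known_parents(persons: pd.DataFrame) -> pd.DataFrame:
    return persons[persons["mother_id"].notna() & persons["father_id"].notna()]


def _ordered_pairs(df: pd.DataFrame, on) -> pd.DataFrame:
    """Self-join on the given key(s); returns ordered (index, relative) id
    pairs with both members' parent ids."""
    cols = ["person_id", "mother_id", "father_id"]
    left = df[cols].rename(columns={"person_id": "index_id"})
    right = df[cols].rename(columns={"person_id": "relative_id"})
    merged = left.merge(right, on=on, suffixes=("_i", "_r"))
    return merged[merged["index_id"] != merged["relative_id"]]


def _twin_pairs(persons: pd.DataFrame, fallback_same_birth_year: bool) -> pd.DataFrame:
    tw = persons[persons["twin_group_id"].notna()]
    tw = _known_parents(tw)
    out = []
    if len(tw):
        cols = ["person_id", "twin_group_id"]
        left = tw[cols].rename(columns={"person_id": "index_id"})
        right = tw[cols].rename(columns={"person_id": "relative_id"})
        m = left.merge(right, on="twin_group_id")
        out.append(m[m["index_id"] != m["relative_id"]][["index_id", "relative_id"]])
    if fallback_same_birth_year:
        # year-level fallback cannot distinguish twins from same-year
        # singleton siblings; opt-in only
        kp = _known_parents(persons[persons["twin_group_id"].isna()])
        m = _ordered_pairs(kp.assign(_by=kp["birth_year"]),
                           on=["mother_id", "father_id"])
        by = persons.set_index("person_id")["birth_year"]
        same = (by.reindex(m["index_id"]).to_numpy()
                == by.reindex(m["relative_id"]).to_numpy())
        out.append(m[same][["index_id", "relative_id"]])
    if not out:
        return pd.DataFrame(columns=["index_id", "relative_id"])
    return pd.concat(out, ignore_index=True).drop_duplicates()


def build_pairs(
    registry: Registry,
    relation: str,
    twin_fallback_same_birth_year: bool = False,
    twin_resemblance: float = RESEMBLANCE["twin"],
) -> pd.DataFrame:
    """Extract the double-entered pair table for one relationship class.

    Output columns: index_id, relative_id, relation, resemblance.  Persons
    with an unknown parent contribute no pairs.  Twin pairs are excluded
    from the full-sibling set; half-siblings share exactly one parent;
    cousins' linking parents are full siblings.
    """
    if relation not in RELATIONS:
        raise PairError(f"unknown relation {relation!r}; expected one of {RELATIONS}")
    persons = registry.persons
    kp = _known_parents(persons)

    if relation == "twin":
        pairs = _twin_pairs(persons, twin_fallback_same_birth_year)
        resemblance = twin_resemblance
    elif relation == "full_sibling":
        sibs = _ordered_pairs(kp, on=["mother_id", "father_id"])[
            ["index_id", "relative_id"]]
        twins = _twin_pairs(persons, twin_fallback_same_birth_year)
        if len(twins):
            key = sibs["index_id"] + "\x00" + sibs["relative_id"]
            tkey = set(twins["index_id"] + "\x00" + twins["relative_id"])
            sibs = sibs[~key.isin(tkey)]
        pairs = sibs
        resemblance = RESEMBLANCE["full_sibling"]
    elif relation == "half_sibling":
        via_mother = _ordered_pairs(kp, on="mother_id")
        via_mother = via_mother[via_mother["father_id_i"] != via_mother["father_id_r"]]
        via_father = _ordered_pairs(kp, on="father_id")
        via_father = via_father[via_father["mother_id_i"] != via_father["mother_id_r"]]
        pairs = pd.concat([
            via_mother[["index_id", "relative_id"]],
            via_father[["index_id", "relative_id"]],
        ], ignore_index=True).drop_duplicates()
        resemblance = RESEMBLANCE["half_sibling"]
    else:  # cousin
        parent_sibs = _ordered_pairs(kp, on=["mother_id", "father_id"])[
            ["index_id", "relative_id"]].rename(
            columns={"index_id": "parent_i", "relative_id": "parent_r"})
        child_parent = pd.concat([
            kp[["person_id", "mother_id"]].rename(columns={"mother_id": "parent"}),
            kp[["person_id", "father_id"]].rename(columns={"father_id": "parent"}),
        ], ignore_index=True)
        step = parent_sibs.merge(
            child_parent.rename(columns={"person_id": "index_id", "parent": "parent_i"}),
            on="parent_i")
        both = step.merge(
            child_parent.rename(columns={"person_id": "relative_id", "parent": "parent_r"}),
            on="parent_r")
        both = both[both["index_id"] != both["relative_id"]]
        # drop pairs that share a parent (those are siblings/half-siblings)
        par = kp.set_index("person_id")[["mother_id", "father_id"]]
        mi = par["mother_id"].reindex(both["index_id"]).to_numpy()
        fi = par["father_id"].reindex(both["index_id"]).to_numpy()
        mr = par["mother_id"].reindex(both["relative_id"]).to_numpy()
        fr = par["father_id"].reindex(both["relative_id"]).to_numpy()
        shares = (mi == mr) | (fi == fr) | (mi == fr) | (fi == mr)
        pairs = both[~shares][["index_id", "relative_id"]].drop_duplicates()
        resemblance = RESEMBLANCE["cousin"]

    out = pairs.reset_index(drop=True).copy()
    out["relation"] = relation
    out["resemblance"] = resemblance
    return out[PAIR_COLUMNS]


def build_all_pairs(registry: Registry, relations: Iterable[str] = RELATIONS,
                    **kwargs) -> pd.DataFrame:
    """All relationship datasets concatenated (a person may appear in more
    than one)."""
    return pd.concat([build_pairs(registry, r, **kwargs) for r in relations],
                     ignore_index=True)


# ---------------------------------------------------------------------------
# Exclusion rules


@dataclass
class ExclusionRules:
    """Cohort inclusion/exclusion settings.

    ``family_scope`` controls whose death/emigration before ``alive_until``
    disqualifies a pair: "nuclear" (default) checks each member's natal
    nuclear family (both parents plus the children of that couple);
    "members" checks only the two pair members themselves.
    """

    child_birth_range: Tuple[int, int] = (1948, 2005)
    parent_birth_range: Tuple[int, int] = (1932, 1985)
    require_born_in_country: bool = True
    require_parents_born_in_country: bool = True
    min_emigration_age: int = 17
    alive_until: int = 1997
    family_scope: str = "nuclear"


def apply_exclusions(
    pairs: pd.DataFrame,
    registry: Registry,
    rules: Optional[ExclusionRules] = None,
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Drop pairs violating the cohort rules; return (pairs, exclusion log).

    Rules are applied sequentially; the log counts pair rows dropped by each
    rule (a row already dropped is not re-counted by later rules).
    """
    rules = rules or ExclusionRules()
    persons = registry.persons.set_index("person_id")
    log: Dict[str, int] = {}

    birth = persons["birth_year"]
    emig = persons["emigration_year"]
    death = persons["death_year"]

    # person-level flags
    lo, hi = rules.child_birth_range
    ok_birth = (birth >= lo) & (birth <= hi)
    plo, phi = rules.parent_birth_range
    mb = birth.reindex(persons["mother_id"]).to_numpy()
    fb = birth.reindex(persons["father_id"]).to_numpy()
    ok_parent_birth = pd.Series(
        (np.isnan(mb) | ((mb >= plo) & (mb <= phi)))
        & (np.isnan(fb) | ((fb >= plo) & (fb <= phi))),
        index=persons.index)
    ok_born_here = persons["born_in_country"].astype(bool)
    mhere = persons["born_in_country"].reindex(persons["mother_id"]).to_numpy()
    fhere = persons["born_in_country"].reindex(persons["father_id"]).to_numpy()
    ok_parents_here = pd.Series(
        (pd.isna(mhere) | (mhere == True)) & (pd.isna(fhere) | (fhere == True)),  # noqa: E712
        index=persons.index)
    emig_age = emig - birth
    ok_emig_age = emig.isna() | (emig_age >= rules.min_emigration_age)

    gone_early = ((death.notna() & (death < rules.alive_until))
                  | (emig.notna() & (emig < rules.alive_until)))
    if rules.family_scope == "nuclear":
        # a person fails if anyone in their natal nuclear family (either
        # parent or any child of the same couple) died/emigrated early
        fam_key = persons["mother_id"].fillna("") + "\x00" + persons["father_id"].fillna("")
        child_bad = gone_early.groupby(fam_key).transform("any")
        parent_bad = (gone_early.reindex(persons["mother_id"]).fillna(False).to_numpy()
                      | gone_early.reindex(persons["father_id"]).fillna(False).to_numpy())
        has_parents = persons["mother_id"].notna() & persons["father_id"].notna()
        fail_alive = gone_early | (has_parents & (child_bad | parent_bad))
    elif rules.family_scope == "members":
        fail_alive = gone_early
    else:
        raise PairError(f"unknown family_scope {rules.family_scope!r}")

    def pair_fail(person_flag: pd.Series) -> pd.Series:
        f = person_flag.reindex(pairs["index_id"]).to_numpy()
        g = person_flag.reindex(pairs["relative_id"]).to_numpy()
        return pd.Series(np.asarray(f, bool) | np.asarray(g, bool), index=pairs.index)

    checks = [
        ("birth_cohort", ~ok_birth),
        ("parent_birth_cohort", ~ok_parent_birth),
    ]
    if rules.require_born_in_country:
        checks.append(("not_born_in_country", ~ok_born_here))
    if rules.require_parents_born_in_country:
        checks.append(("parents_not_born_in_country", ~ok_parents_here))
    checks.append((f"emigrated_lt_{rules.min_emigration_age}", ~ok_emig_age))
    checks.append((f"family_gone_before_{rules.alive_until}", fail_alive))

    keep = pd.Series(True, index=pairs.index)
    for name, person_fail in checks:
        fail = pair_fail(person_fail) & keep
        log[name] = int(fail.sum())
        keep &= ~fail
    return pairs[keep].reset_index(drop=True), log


# ---------------------------------------------------------------------------
# Double-entry tabulation


@dataclass(frozen=True)
class DoubleEntryTable:
    """2x2 counts of (index affected, relative affected) over double-entered
    pair rows.  Under full double entry n10 == n01."""

    n11: float
    n10: float
    n01: float
    n00: float

    @property
    def total(self) -> float:
        return self.n11 + self.n10 + self.n01 + self.n00

    @property
    def symmetric(self) -> bool:
        return self.n10 == self.n01

    def halved(self) -> "DoubleEntryTable":
        """Single-entry (unordered-pair) counts: every cell is half the
        double-entry cell, with discordant pairs split evenly across the two
        off-diagonal cells (the orientation of an unordered discordant pair is
        arbitrary).  Leaves the tetrachoric point estimate unchanged and
        doubles its variance."""
        return DoubleEntryTable(self.n11 / 2, self.n10 / 2,
                                self.n01 / 2, self.n00 / 2)


def cross_tabulate(pairs: pd.DataFrame, affected: Mapping[str, bool] | pd.Series
                   ) -> DoubleEntryTable:
    """Count (index affected, relative affected) combinations over pair rows."""
    aff = pd.Series(affected)
    ai = aff.reindex(pairs["index_id"]).to_numpy(dtype=bool)
    ar = aff.reindex(pairs["relative_id"]).to_numpy(dtype=bool)
    return DoubleEntryTable(
        n11=int((ai & ar).sum()),
        n10=int((ai & ~ar).sum()),
        n01=int((~ai & ar).sum()),
        n00=int((~ai & ~ar).sum()),
    )


def single_entry(pairs: pd.DataFrame) -> pd.DataFrame:
    """De-duplicate double-entered rows, keeping the orientation whose
    index_id sorts lexicographically before relative_id."""
    keep = pairs["index_id"] < pairs["relative_id"]
    # self-consistent for stray single rows entered in the other orientation
    key_fwd = pairs["index_id"] + "\x00" + pairs["relative_id"] + "\x00" + pairs["relation"]
    key_rev = pairs["relative_id"] + "\x00" + pairs["index_id"] + "\x00" + pairs["relation"]
    have = set(key_fwd)
    keep |= ~key_rev.isin(have)
    return pairs[keep].reset_index(drop=True)


def person_exposure_summary(
    pairs: pd.DataFrame,
    follow: pd.DataFrame,
) -> pd.DataFrame:
    """Per-person exposure classification for one relationship dataset.

    A person is exposed when at least one relative of the class had the
    diagnosis during the study window (baseline, ever-affected convention).
    Returns one row per person appearing in the pair table: affected flag,
    exposed flag, person_years.  ``follow`` is the output of
    :func:`famagg.registry.follow_up_table`.
    """
    aff = follow["event"]
    rel_aff = aff.reindex(pairs["relative_id"]).to_numpy(dtype=bool)
    exposed = (pd.Series(rel_aff, index=pairs["index_id"].to_numpy())
               .groupby(level=0).any())
    out = pd.DataFrame({"exposed": exposed})
    out["affected"] = aff.reindex(out.index).to_numpy(dtype=bool)
    out["person_years"] = follow["person_years"].reindex(out.index).to_numpy()
    out.index.name = "person_id"
    return out
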
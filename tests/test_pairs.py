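"""Pair extraction, exclusion rules and double-entry tabulation."""

import numpy as np
import pandas as pd
import pytest

from famagg import (DoubleEntryTable, ExclusionRules, LiabilityParams,
                    apply_exclusions, build_all_pairs, build_pairs,
                    cross_tabulate, simulate_registry, single_entry)
from famagg.registry import Registry, follow_up_table
from conftest import make_events, make_persons
from oracles import brute_force_kinship


def _pair_set(df):
    return set(zip(df["index_id"], df["relative_id"]))


def test_nuclear_family_full_siblings():
    persons = make_persons([
        ("m", "female", 1960, None, None, None, None, None),
        ("f", "male", 1958, None, None, None, None, None),
        ("k1", "male", 1985, None, None, "m", "f", None),
        ("k2", "female", 1988, None, None, "m", "f", None),
    ])
    reg = Registry(persons=persons, events=make_events([]))
    sibs = build_pairs(reg, "full_sibling")
    assert _pair_set(sibs) == {("k1", "k2"), ("k2", "k1")}
    assert (sibs["resemblance"] == 0.5).all()


def test_half_siblings_share_one_parent():
    persons = make_persons([
        ("f", "male", 1958, None, None, None, None, None),
        ("m1", "female", 1960, None, None, None, None, None),
        ("m2", "female", 1962, None, None, None, None, None),
        ("a", "male", 1985, None, None, "m1", "f", None),
        ("b", "female", 1990, None, None, "m2", "f", None),
    ])
    reg = Registry(persons=persons, events=make_events([]))
    half = build_pairs(reg, "half_sibling")
    assert _pair_set(half) == {("a", "b"), ("b", "a")}
    assert len(build_pairs(reg, "full_sibling")) == 0


def test_cousins_via_full_sibling_mothers():
    persons = make_persons([
        ("gm", "female", 1935, None, None, None, None, None),
        ("gf", "male", 1933, None, None, None, None, None),
        ("m1", "female", 1960, None, None, "gm", "gf", None),
        ("m2", "female", 1962, None, None, "gm", "gf", None),
        ("f1", "male", 1959, None, None, None, None, None),
        ("f2", "male", 1961, None, None, None, None, None),
        ("x", "male", 1985, None, None, "m1", "f1", None),
        ("y", "female", 1988, None, None, "m2", "f2", None),
    ])
    reg = Registry(persons=persons, events=make_events([]))
    cousins = build_pairs(reg, "cousin")
    assert _pair_set(cousins) == {("x", "y"), ("y", "x")}
    assert (cousins["resemblance"] == 0.125).all()


def test_pedigree_matches_brute_force_oracle(pedigree_registry):
    """All four relationship sets equal the O(n^2) exhaustive classifier."""
    oracle = brute_force_kinship(pedigree_registry.persons)
    for rel in ("twin", "full_sibling", "half_sibling", "cousin"):
        got = _pair_set(build_pairs(pedigree_registry, rel))
        assert got == oracle[rel], rel
    # sanity on the fixture design: every relationship is present
    assert oracle["twin"] and oracle["half_sibling"] and oracle["cousin"]
    # twins never appear in the sibling set
    assert not (_pair_set(build_pairs(pedigree_registry, "full_sibling"))
                & oracle["twin"])


def test_simulated_registry_matches_brute_force_oracle():
    """Merge-based extraction equals the exhaustive classifier on a
    simulated registry of ~200 persons."""
    params = LiabilityParams(n_families=18, twin_sibship_prob=0.3,
                             repartner_prob=0.5, seed=5)
    reg, _ = simulate_registry(params)
    assert len(reg.persons) <= 230
    oracle = brute_force_kinship(reg.persons)
    for rel in ("twin", "full_sibling", "half_sibling", "cousin"):
        assert _pair_set(build_pairs(reg, rel)) == oracle[rel], rel


def test_double_entry_symmetry():
    params = LiabilityParams(n_families=300, twin_sibship_prob=0.1, seed=3)
    reg, _ = simulate_registry(params)
    pairs = build_all_pairs(reg)
    fwd = set(zip(pairs["index_id"], pairs["relative_id"], pairs["relation"]))
    rev = set(zip(pairs["relative_id"], pairs["index_id"], pairs["relation"]))
    assert fwd == rev
    assert not (pairs["index_id"] == pairs["relative_id"]).any()


def test_relation_sets_disjoint():
    params = LiabilityParams(n_families=200, twin_sibship_prob=0.2,
                             repartner_prob=0.4, seed=4)
    reg, _ = simulate_registry(params)
    seen = {}
    for rel in ("twin", "full_sibling", "half_sibling", "cousin"):
        for key in _pair_set(build_pairs(reg, rel)):
            assert key not in seen, (key, rel, seen.get(key))
            seen[key] = rel


# -- exclusions ---------------------------------------------------------


def _sib_registry(**overrides):
    rows = {
        "m": ("m", "female", 1955, None, None, None, None, None),
        "f": ("f", "male", 1953, None, None, None, None, None),
        "a": ("a", "male", 1980, None, None, "m", "f", None),
        "b": ("b", "female", 1984, None, None, "m", "f", None),
    }
    rows.update(overrides)
    return Registry(persons=make_persons(list(rows.values())),
                    events=make_events([]))


def test_emigration_before_17_drops_pair():
    reg = _sib_registry(a=("a", "male", 1980, None, 1995, "m", "f", None))
    pairs = build_pairs(reg, "full_sibling")
    kept, log = apply_exclusions(pairs, reg)
    assert len(kept) == 0
    assert log["emigrated_lt_17"] == 2


def test_family_death_before_1997_drops_pairs():
    reg = _sib_registry(b=("b", "female", 1984, 1990, None, "m", "f", None))
    pairs = build_pairs(reg, "full_sibling")
    kept, log = apply_exclusions(pairs, reg)
    assert len(kept) == 0
    assert log["family_gone_before_1997"] == 2


def test_compliant_family_is_noop():
    reg = _sib_registry()
    pairs = build_pairs(reg, "full_sibling")
    kept, log = apply_exclusions(pairs, reg)
    assert len(kept) == len(pairs) == 2
    assert all(v == 0 for v in log.values())


def test_member_scope_keeps_pair_when_only_sibling_died():
    """With family_scope='members' an early parent death does not disqualify
    the children, but with 'nuclear' it does."""
    reg = _sib_registry(f=("f", "male", 1953, 1990, None, None, None, None))
    pairs = build_pairs(reg, "full_sibling")
    kept_members, _ = apply_exclusions(
        pairs, reg, ExclusionRules(family_scope="members"))
    assert len(kept_members) == 2
    kept_nuclear, _ = apply_exclusions(pairs, reg)
    assert len(kept_nuclear) == 0


def test_birth_cohort_rule():
    reg = _sib_registry(a=("a", "male", 1940, None, None, "m", "f", None))
    pairs = build_pairs(reg, "full_sibling")
    kept, log = apply_exclusions(pairs, reg)
    assert len(kept) == 0 and log["birth_cohort"] == 2


# -- double-entry tabulation -------------------------------------------


def test_cross_tabulate_concordant_pair():
    pairs = pd.DataFrame({"index_id": ["a", "b"], "relative_id": ["b", "a"],
                          "relation": "twin", "resemblance": 0.66})
    tab = cross_tabulate(pairs, pd.Series({"a": True, "b": True}))
    assert (tab.n11, tab.n10, tab.n01, tab.n00) == (2, 0, 0, 0)


def test_cross_tabulate_discordant_pair_is_symmetric():
    pairs = pd.DataFrame({"index_id": ["a", "b"], "relative_id": ["b", "a"],
                          "relation": "twin", "resemblance": 0.66})
    tab = cross_tabulate(pairs, pd.Series({"a": True, "b": False}))
    assert (tab.n11, tab.n10, tab.n01, tab.n00) == (0, 1, 1, 0)
    assert tab.symmetric


def test_cross_tabulate_matches_brute_force():
    """Vectorised tabulation equals an explicit loop over ordered pairs,
    and full double entry forces n10 == n01."""
    rng = np.random.default_rng(0)
    people = [f"p{i}" for i in range(60)]
    aff = pd.Series(rng.random(60) < 0.3, index=people)
    rows = []
    for _ in range(100):
        i, j = rng.choice(60, 2, replace=False)
        rows.append((people[i], people[j]))
        rows.append((people[j], people[i]))
    pairs = pd.DataFrame(rows, columns=["index_id", "relative_id"])
    pairs["relation"] = "full_sibling"
    pairs["resemblance"] = 0.5
    tab = cross_tabulate(pairs, aff)
    counts = {"11": 0, "10": 0, "01": 0, "00": 0}
    for i, j in zip(pairs["index_id"], pairs["relative_id"]):
        counts[f"{int(aff[i])}{int(aff[j])}"] += 1
    assert (tab.n11, tab.n10, tab.n01, tab.n00) == (
        counts["11"], counts["10"], counts["01"], counts["00"])
    assert tab.symmetric
    assert tab.total == len(pairs)


def test_single_entry_halves_rows():
    params = LiabilityParams(n_families=100, seed=9)
    reg, _ = simulate_registry(params)
    pairs = build_all_pairs(reg)
    se = single_entry(pairs)
    assert len(se) == len(pairs) // 2
    # one orientation per unordered pair
    keys = set(map(frozenset, zip(se["index_id"], se["relative_id"])))
    assert len(keys) == len(se)
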
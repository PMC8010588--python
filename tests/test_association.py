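"""Incidence rates, odds ratios, interaction, trend and sensitivity."""

import numpy as np
import pandas as pd
import pytest

from famagg import (EstimationError, ExposureSummary, FamilialAggregation,
                    FitError, LiabilityParams, adjusted_or, build_all_pairs,
                    crude_or, incidence_rate, incidence_rate_ratio,
                    pearson_trend, resemblance_interaction,
                    sensitivity_filters, simulate_association_rows,
                    simulate_registry, stratify)
from famagg.association import sex_pair_label
from famagg.registry import Registry
from conftest import make_events, make_persons


# -- incidence rates ----------------------------------------------------


@pytest.mark.parametrize("cases,py,expected", [
    (14, 4527, 3.09),       # twin-affected stratum of the familial-risk table
    (445, 224_009, 1.99),   # half-sibling-affected stratum
    (723, 302_075, 2.39),   # sibling-affected stratum
    (1935, 1_292_858, 1.50),  # cousin-affected stratum
])
def test_incidence_rate_published_strata(cases, py, expected):
    est = incidence_rate(cases, py)
    assert round(est.value, 2) == expected


def test_incidence_rate_zero_events():
    est = incidence_rate(0, 1000)
    assert est.value == 0.0 and est.ci_low == 0.0 and est.ci_high > 0


def test_incidence_rate_poisson_ci():
    est = incidence_rate(14, 4527)
    assert round(est.ci_low, 2) == 1.69  # exact Poisson (chi-square) bounds
    assert round(est.ci_high, 2) == 5.19


def test_incidence_rate_requires_exposure():
    with pytest.raises(EstimationError):
        incidence_rate(3, 0.0)


def test_irr_identity_and_doubling():
    a = ExposureSummary(cases=10, persons_at_risk=100, person_years=1000.0)
    b = ExposureSummary(cases=10, persons_at_risk=100, person_years=1000.0)
    assert incidence_rate_ratio(a, b).value == pytest.approx(1.0)
    c = ExposureSummary(cases=20, persons_at_risk=100, person_years=1000.0)
    assert incidence_rate_ratio(c, b).value == pytest.approx(2.0)


def test_irr_zero_unexposed_flagged():
    a = ExposureSummary(cases=5, persons_at_risk=50, person_years=100.0)
    b = ExposureSummary(cases=0, persons_at_risk=50, person_years=100.0)
    with pytest.raises(EstimationError, match="zero cases"):
        incidence_rate_ratio(a, b)


# -- odds ratios --------------------------------------------------------


def test_crude_or_symmetric_table_is_one():
    est = crude_or(10, 20, 10, 20)
    assert est.value == pytest.approx(1.0)


def test_crude_or_zero_cell_continuity():
    with pytest.warns(UserWarning, match="Haldane"):
        est = crude_or(0, 10, 5, 100)
    assert est.note == "haldane_anscombe_0.5"
    assert est.value > 0


def test_crude_or_equals_person_level_brute_force():
    """Model OR on a small simulated registry equals the odds ratio computed
    by looping over raw person rows."""
    params = LiabilityParams(n_families=800, h2=0.5, c2=0.2, seed=6)
    reg, _ = simulate_registry(params)
    model = FamilialAggregation.from_registry(reg)
    res = model.fit(adjust=())
    rel = "full_sibling"
    exp_s, unexp_s = model.exposure_summaries(rel)
    # brute force from raw rows
    rows = model.pair_rows[model.pair_rows["relation"] == rel]
    by_person = {}
    for r in rows.itertuples():
        rec = by_person.setdefault(r.index_id, {"aff": bool(r.index_affected),
                                                "exp": False})
        rec["exp"] = rec["exp"] or bool(r.relative_affected)
    a = sum(1 for v in by_person.values() if v["exp"] and v["aff"])
    b = sum(1 for v in by_person.values() if v["exp"] and not v["aff"])
    c = sum(1 for v in by_person.values() if not v["exp"] and v["aff"])
    d = sum(1 for v in by_person.values() if not v["exp"] and not v["aff"])
    assert (exp_s.cases, exp_s.persons_at_risk) == (a, a + b)
    assert (unexp_s.cases, unexp_s.persons_at_risk) == (c, c + d)
    want = (a / b) / (c / d)
    assert res.get("OR_crude", rel).value == pytest.approx(want)


def test_adjusted_recovers_planted_exposure_effect():
    """Logistic OR recovers a planted beta within 2 SE at n = 100 000."""
    beta = np.log(2.0)
    rows = simulate_association_rows(100_000, beta_exposure=beta, seed=10)
    est = adjusted_or(rows.rename(columns={})
                      .assign(index_id="x", relative_id="y"))
    assert abs(np.log(est.value) - beta) < 2 * est.se


def test_adjusted_close_to_crude_without_confounding():
    """Covariates independent of exposure and outcome leave the OR unmoved."""
    rows = simulate_association_rows(60_000, beta_exposure=np.log(1.8), seed=11)
    adj = adjusted_or(rows)
    crude = adjusted_or(rows, adjust=())
    assert np.log(adj.value) == pytest.approx(np.log(crude.value),
                                              abs=2 * crude.se)


def test_single_sex_subset_drops_sex_covariate():
    rows = simulate_association_rows(20_000, beta_exposure=np.log(2), seed=12)
    rows = rows[rows["index_sex"] == "female"]
    est = adjusted_or(rows)  # would be singular if sex stayed in the design
    assert est.value > 1


# -- interaction --------------------------------------------------------


def _interaction_rows(beta_by_relation, n=40_000, seed=0):
    rng = np.random.default_rng(seed)
    rels = {"twin": 0.66, "full_sibling": 0.5, "half_sibling": 0.25,
            "cousin": 0.125}
    rel = rng.choice(list(rels), size=n)
    g = np.array([rels[r] for r in rel])
    exposure = rng.random(n) < 0.05
    logit = -3.6 + beta_by_relation * g * exposure
    y = rng.random(n) < 1 / (1 + np.exp(-logit))
    return pd.DataFrame({
        "relation": rel, "resemblance": g,
        "relative_affected": exposure, "index_affected": y,
        "index_sex": "female", "relative_sex": "female"})


def test_interaction_recovers_planted_slope():
    rows = _interaction_rows(beta_by_relation=2.0, n=400_000, seed=1)
    est = resemblance_interaction(rows)
    assert abs(np.log(est.value) - 2.0) < 2.5 * est.se


def test_interaction_requires_multiple_relations():
    rows = _interaction_rows(1.0, n=1000, seed=2)
    rows = rows[rows["relation"] == "cousin"]
    with pytest.raises(EstimationError, match="relationship classes"):
        resemblance_interaction(rows)


def test_interaction_null_when_resemblance_shuffled():
    """Permuting resemblance across relationship labels destroys the
    interaction signal."""
    rows = _interaction_rows(beta_by_relation=2.0, n=200_000, seed=3)
    rng = np.random.default_rng(0)
    shuffled = rows.copy()
    shuffled["resemblance"] = rng.permutation(shuffled["resemblance"].to_numpy())
    est = resemblance_interaction(shuffled)
    assert abs(np.log(est.value)) < 3 * est.se


# -- pearson trend ------------------------------------------------------


def test_pearson_trend_on_published_tetrachoric_ladder():
    """The printed resemblance/tetrachoric ladder is strongly positively
    correlated."""
    est = pearson_trend([0.66, 0.5, 0.25, 0.125], [0.17, 0.11, 0.05, 0.02])
    assert est.value > 0.9


def test_pearson_trend_exact_linearity():
    est = pearson_trend([0.125, 0.25, 0.5], [1.0, 2.0, 4.0])
    assert est.value == pytest.approx(
        np.corrcoef([0.125, 0.25, 0.5], [1, 2, 4])[0, 1])


def test_pearson_trend_degenerate_inputs():
    with pytest.raises(EstimationError):
        pearson_trend([0.5, 0.25], [1.0, 2.0])
    with pytest.raises(EstimationError):
        pearson_trend([0.66, 0.5, 0.25], [1.0, 1.0, 1.0])


# -- stratification -----------------------------------------------------


def test_sex_pair_labels():
    idx = pd.Series(["male", "female", "male"])
    rel = pd.Series(["male", "female", "female"])
    assert list(sex_pair_label(idx, rel)) == ["male-male", "female-female",
                                              "opposite-sex"]


def test_stratified_recovery_of_sex_specific_effect():
    """A planted male-male OR twice the female-female OR is recovered in the
    right order."""
    rows = simulate_association_rows(
        300_000, beta_exposure=np.log(1.5),
        beta_by_sex_pair={"male-male": np.log(3.0),
                          "female-female": np.log(1.5),
                          "opposite": np.log(1.0)},
        seed=13)
    rows = rows.assign(index_id="x", relative_id="y")
    ests = {e.stratum: e for e in stratify(rows, "sex_pair", adjusted_or,
                                           adjust=())}
    assert (ests["male-male"].value > ests["female-female"].value
            > ests["opposite-sex"].value)


def test_empty_stratum_yields_na():
    rows = simulate_association_rows(500, beta_exposure=0.0, seed=14)
    rows = rows.assign(index_id="x", relative_id="y")
    rows.loc[:, "index_affected"] = False  # no cases anywhere -> fits fail
    out = stratify(rows, "sex_pair", adjusted_or, adjust=())
    assert all(np.isnan(e.value) for e in out)
    assert all(e.note for e in out)


# -- sensitivity --------------------------------------------------------


@pytest.fixture(scope="module")
def small_fit():
    params = LiabilityParams(n_families=1200, h2=0.5, c2=0.1,
                             twin_sibship_prob=0.05, seed=8)
    reg, _ = simulate_registry(params)
    pairs = build_all_pairs(reg)
    return reg, pairs


def test_single_vs_double_entry(small_fit):
    """Identical point estimates, wider CIs under single entry."""
    reg, pairs = small_fit
    model = FamilialAggregation.from_registry(reg, pairs=pairs)
    double = model.fit(adjust=())
    single = model.fit(adjust=(), single_entry_mode=True)
    rel = "full_sibling"
    d, s = double.get("OR_crude", rel), single.get("OR_crude", rel)
    assert d.value == pytest.approx(s.value)          # person-level: identical
    dt, st_ = double.get("tetrachoric", rel), single.get("tetrachoric", rel)
    assert dt.value == pytest.approx(st_.value, abs=1e-9)
    assert st_.se > dt.se                             # half the information
    da, sa = double.get("OR_adjusted", rel), single.get("OR_adjusted", rel)
    assert sa.se > da.se


def test_differential_exclusion_noop_without_codes(small_fit):
    reg, pairs = small_fit
    # strip any differential codes from the registry
    clean = Registry(
        persons=reg.persons,
        events=reg.events[reg.events["code"] == "R559"].reset_index(drop=True))
    variant, delta = sensitivity_filters(clean, pairs, "exclude_differential_dx",
                                         adjust=())
    assert np.nanmax(np.abs(delta["delta"].to_numpy(dtype=float))) == 0.0


def test_differential_exclusion_drops_carrier_family():
    persons = make_persons([
        ("m", "female", 1955, None, None, None, None, None),
        ("f", "male", 1953, None, None, None, None, None),
        ("a", "male", 1980, None, None, "m", "f", None),
        ("b", "female", 1984, None, None, "m", "f", None),
        ("m2", "female", 1955, None, None, None, None, None),
        ("f2", "male", 1953, None, None, None, None, None),
        ("c", "male", 1980, None, None, "m2", "f2", None),
        ("d", "female", 1984, None, None, "m2", "f2", None),
    ])
    events = make_events([("a", "DIFF_TLOC", 2001, "inpatient"),
                          ("c", "R559", 2003, "primary_care")])
    reg = Registry(persons=persons, events=events)
    from famagg.association import differential_family_filter
    from famagg import build_pairs
    pairs = build_pairs(reg, "full_sibling")
    kept = differential_family_filter(reg, pairs)
    assert set(kept["index_id"]) == {"c", "d"}
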
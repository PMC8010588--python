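"""Synthetic multigeneration registry with a liability-threshold trait.

The generator emits three-generation extended families: a grandparent couple
with two children (full siblings) who each partner a founder and raise their
own children.  Children of the two sibships are first cousins; optional
re-partnering of one parent produces maternal/paternal half-siblings; a
configurable fraction of sibships are twin births with latent MZ/DZ zygosity.

The binary diagnosis arises from a liability-threshold model.  Each person's
liability is L = A + C + E with Var(A) = h2 (additive genetic), Var(C) = c2
(environment shared within the rearing household), Var(E) = 1 - h2 - c2.
Additive values are propagated through the pedigree (child = mid-parent plus
Mendelian-segregation noise of variance h2/2), which makes the additive
correlation of a relative pair equal to its genetic resemblance g, and the
liability correlation g*h2 (+ c2 for pairs reared in the same household).
A female liability shift produces the female excess in diagnosed risk; the
diagnosis threshold is calibrated numerically so that the marginal diagnosed
fraction matches the target prevalence.

Age at first event is log-normal (median ~22 years, IQR ~16-33), truncated to
the person's follow-up window so every liability-affected, uncensored person
is observed as diagnosed.  Death and emigration censoring, differential
(non-reflex) transient-loss-of-consciousness codes and repeat syncope events
are applied at configurable rates.

The ground truth (per-person liability components, twin zygosity, calibrated
threshold) is returned alongside the registry for parameter-recovery testing
and is never consumed by the analysis pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .registry import Registry, STUDY_START, STUDY_END, SYNCOPE_CODE

#: Expected allele-sharing fraction by relationship (genetic theory constants).
GENETIC_RESEMBLANCE: Dict[str, float] = {
    "mz_twin": 1.0,
    "dz_twin": 0.5,
    "full_sibling": 0.5,
    "half_sibling": 0.25,
    "cousin": 0.125,
}

#: Code emitted for differential (non-reflex) TLOC diagnoses.
DIFFERENTIAL_CODE = "DIFF_TLOC"

_SOURCE_LEVELS = ("primary_care", "inpatient", "outpatient")
_SOURCE_PROBS = (0.4811, 0.1974, 0.3215)


class ParameterError(ValueError):
    """Infeasible simulator settings (e.g. h2 + c2 > 1)."""


@dataclass
class LiabilityParams:
    """Simulator settings.

    Defaults emulate the study conditions of a nationwide register cohort:
    2.3% diagnosed prevalence over 1997-2015 follow-up, a tetrachoric ladder
    consistent with h2 = 0.20 and c2 = 0.01, a female liability shift that
    yields female ~2.9% vs male ~1.7% prevalence, 31% MZ among twin pairs
    (which reproduces a Weinberg mean resemblance near 0.66), and a ~2%
    differential-diagnosis fraction among cases.
    """

    n_families: int = 5000
    target_prevalence: float = 0.023
    h2: float = 0.20
    c2: float = 0.01
    female_liability_shift: float = 0.22
    mz_fraction_of_twins: float = 0.31
    twin_sibship_prob: float = 0.015
    repartner_prob: float = 0.10
    third_child_prob: float = 0.30
    death_prob: float = 0.03
    emigration_prob: float = 0.02
    differential_dx_frac: float = 0.0207
    repeat_event_prob: float = 0.2
    onset_median_age: float = 22.0
    onset_log_sigma: float = 0.54
    study_start: int = STUDY_START
    study_end: int = STUDY_END
    seed: int = 0
    resemblance_map: Dict[str, float] = field(
        default_factory=lambda: dict(GENETIC_RESEMBLANCE))

    def validate(self) -> None:
        if self.h2 < 0 or self.c2 < 0 or self.h2 + self.c2 > 1:
            raise ParameterError(
                f"need h2 >= 0, c2 >= 0, h2 + c2 <= 1 (got h2={self.h2}, c2={self.c2})")
        for name in ("target_prevalence", "mz_fraction_of_twins",
                     "twin_sibship_prob", "repartner_prob", "third_child_prob",
                     "death_prob", "emigration_prob", "differential_dx_frac",
                     "repeat_event_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 < self.target_prevalence < 1.0:
            raise ParameterError("target_prevalence must lie in (0, 1)")
        if self.resemblance_map != GENETIC_RESEMBLANCE:
            raise ParameterError("resemblance_map values are genetic-theory "
                                 "constants and cannot be changed")


@dataclass
class SyntheticTruth:
    """Ground truth emitted next to a simulated registry (never consumed by
    the analysis pipeline)."""

    liabilities: pd.DataFrame  # person_id, A, C, E, liability, affected
    zygosity: pd.DataFrame     # twin_group_id, zygosity
    threshold: float
    params: LiabilityParams


def calibrate_threshold(params: LiabilityParams) -> float:
    """Liability threshold such that the sex-averaged diagnosed fraction
    equals the target prevalence (root-finding on the marginal normal)."""
    s, p = params.female_liability_shift, params.target_prevalence

    def f(tau: float) -> float:
        return 0.5 * (norm.sf(tau) + norm.sf(tau - s)) - p

    return float(brentq(f, -10.0, 10.0))


def sex_assignment(pair_type: str, zygosity: Optional[str],
                   rng: np.random.Generator) -> Tuple[str, str]:
    """Sexes for one relative pair: MZ twins are always same-sex; DZ twins
    and every other pair type are independent fair draws."""
    if pair_type == "twin" and zygosity is None:
        raise ParameterError("twin pairs require known zygosity")
    if pair_type == "twin" and zygosity == "mz":
        s = "female" if rng.random() < 0.5 else "male"
        return s, s
    draws = rng.random(2) < 0.5
    return tuple("female" if d else "male" for d in draws)  # type: ignore


def _truncated_lognormal(rng, mu, sigma, lo, hi):
    """Inverse-CDF sample of lognormal(mu, sigma) truncated to [lo, hi]."""
    a = np.where(lo <= 0, 0.0, norm.cdf((np.log(np.maximum(lo, 1e-9)) - mu) / sigma))
    b = norm.cdf((np.log(np.maximum(hi, 1e-9)) - mu) / sigma)
    b = np.maximum(b, a + 1e-12)
    u = a + (b - a) * rng.random(len(np.atleast_1d(lo)))
    return np.exp(mu + sigma * norm.ppf(u))


def simulate_registry(params: LiabilityParams) -> Tuple[Registry, SyntheticTruth]:
    """Generate a registry plus ground truth under the liability model.

    All random draws use a single seeded generator in a fixed order, so the
    same params (including seed) reproduce the registry byte-for-byte.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_families
    h2, c2 = params.h2, params.c2
    e2 = 1.0 - h2 - c2
    sd_a = np.sqrt(h2)
    sd_mendel = np.sqrt(h2 / 2.0)
    sd_c = np.sqrt(c2)
    sd_e = np.sqrt(e2)

    fam = np.arange(n)

    # --- grandparent couple -------------------------------------------
    gpm_birth = rng.integers(1930, 1950, n)
    gpf_birth = gpm_birth + rng.integers(-3, 4, n)
    # --- parent generation: two full-sib parents + founder spouses ----
    p1_birth = gpm_birth + rng.integers(20, 31, n)
    p2_birth = gpm_birth + rng.integers(20, 31, n)
    p1_sex_f = rng.random(n) < 0.5
    p2_sex_f = rng.random(n) < 0.5
    s1_birth = p1_birth + rng.integers(-3, 4, n)
    s2_birth = p2_birth + rng.integers(-3, 4, n)

    # additive genetic values
    a_gpf = rng.normal(0.0, sd_a, n)
    a_gpm = rng.normal(0.0, sd_a, n)
    a_p1 = 0.5 * (a_gpf + a_gpm) + rng.normal(0.0, sd_mendel, n)
    a_p2 = 0.5 * (a_gpf + a_gpm) + rng.normal(0.0, sd_mendel, n)
    a_s1 = rng.normal(0.0, sd_a, n)
    a_s2 = rng.normal(0.0, sd_a, n)

    # household shared environments
    c_gp = rng.normal(0.0, sd_c, n)      # grandparent household (rears p1, p2)
    c_n1 = rng.normal(0.0, sd_c, n)      # nuclear household 1
    c_n2 = rng.normal(0.0, sd_c, n)      # nuclear household 2
    c_rp = rng.normal(0.0, sd_c, n)      # re-partner household

    # --- sibship structure --------------------------------------------
    twin1 = rng.random(n) < params.twin_sibship_prob
    twin2 = rng.random(n) < params.twin_sibship_prob
    third1 = (~twin1) & (rng.random(n) < params.third_child_prob)
    third2 = (~twin2) & (rng.random(n) < params.third_child_prob)
    mz1 = twin1 & (rng.random(n) < params.mz_fraction_of_twins)
    mz2 = twin2 & (rng.random(n) < params.mz_fraction_of_twins)
    repart = rng.random(n) < params.repartner_prob
    s1b_birth = p1_birth + rng.integers(-3, 6, n)
    a_s1b = rng.normal(0.0, sd_a, n)

    # child birth offsets (years after the later-born partner)
    def child_birth(pb, sb, off):
        return np.minimum(np.maximum(pb, sb) + off, 2005)

    off1 = rng.integers(20, 31, n)
    off1b = off1 + rng.integers(1, 6, n)   # younger full sib / third child
    off1c = off1b + rng.integers(1, 5, n)
    off2 = rng.integers(20, 31, n)
    off2b = off2 + rng.integers(1, 6, n)
    off2c = off2b + rng.integers(1, 5, n)
    off_rp = off1c + rng.integers(1, 6, n)

    # pre-draw per-family child attributes in fixed order
    def draw_children(a_par, a_sp, twin, mz, pb, sb, off_first, off_second, off_third):
        births = {}
        births["b1"] = child_birth(pb, sb, off_first)
        births["b2"] = np.where(twin, births["b1"], child_birth(pb, sb, off_second))
        births["b3"] = child_birth(pb, sb, off_third)
        mid = 0.5 * (a_par + a_sp)
        men1 = rng.normal(0.0, sd_mendel, n)
        men2 = rng.normal(0.0, sd_mendel, n)
        men3 = rng.normal(0.0, sd_mendel, n)
        a1 = mid + men1
        a2 = np.where(mz, a1, mid + men2)   # MZ co-twins share A exactly
        a3 = mid + men3
        sex1 = rng.random(n) < 0.5
        sex2_raw = rng.random(n) < 0.5
        sex2 = np.where(mz, sex1, sex2_raw)  # MZ same-sex, all else independent
        sex3 = rng.random(n) < 0.5
        return births, (a1, a2, a3), (sex1, sex2, sex3)

    b1, a_c1, sex_c1 = draw_children(a_p1, a_s1, twin1, mz1, p1_birth,
                                     s1_birth, off1, off1b, off1c)
    b2, a_c2, sex_c2 = draw_children(a_p2, a_s2, twin2, mz2, p2_birth,
                                     s2_birth, off2, off2b, off2c)
    # re-partner child of parent 1 with new spouse
    a_rp = 0.5 * (a_p1 + a_s1b) + rng.normal(0.0, sd_mendel, n)
    sex_rp = rng.random(n) < 0.5
    b_rp = child_birth(p1_birth, s1b_birth, off_rp)

    # --- assemble person blocks ---------------------------------------
    def ids(tag):
        return np.char.add(np.char.add("F", fam.astype(str)), "_" + tag)

    blocks = []

    def add_block(mask, pid, sexf, birth, mother, father, a, c, twin_gid=None):
        m = np.asarray(mask)
        if not m.any():
            return
        blocks.append(pd.DataFrame({
            "person_id": pid[m],
            "sex": np.where(sexf[m], "female", "male"),
            "birth_year": birth[m].astype(int),
            "mother_id": mother[m] if isinstance(mother, np.ndarray) else mother,
            "father_id": father[m] if isinstance(father, np.ndarray) else father,
            "A": a[m],
            "C": c[m],
            "twin_group_id": twin_gid[m] if twin_gid is not None else None,
        }))

    true_ = np.ones(n, bool)
    none_ids = np.array([None] * n, object)
    gpf_id, gpm_id = ids("GPF"), ids("GPM")
    add_block(true_, gpf_id, np.zeros(n, bool), gpf_birth, none_ids, none_ids,
              a_gpf, rng.normal(0.0, sd_c, n))
    add_block(true_, gpm_id, np.ones(n, bool), gpm_birth, none_ids, none_ids,
              a_gpm, rng.normal(0.0, sd_c, n))

    p1_id, p2_id = ids("P1"), ids("P2")
    add_block(true_, p1_id, p1_sex_f, p1_birth, gpm_id, gpf_id, a_p1, c_gp)
    add_block(true_, p2_id, p2_sex_f, p2_birth, gpm_id, gpf_id, a_p2, c_gp)
    s1_id, s2_id, s1b_id = ids("S1"), ids("S2"), ids("S1B")
    add_block(true_, s1_id, ~p1_sex_f, s1_birth, none_ids, none_ids, a_s1,
              rng.normal(0.0, sd_c, n))
    add_block(true_, s2_id, ~p2_sex_f, s2_birth, none_ids, none_ids, a_s2,
              rng.normal(0.0, sd_c, n))
    add_block(repart, s1b_id, ~p1_sex_f, s1b_birth, none_ids, none_ids, a_s1b,
              rng.normal(0.0, sd_c, n))

    def couple(parent_f, parent_id, spouse_id):
        mother = np.where(parent_f, parent_id, spouse_id)
        father = np.where(parent_f, spouse_id, parent_id)
        return mother, father

    mo1, fa1 = couple(p1_sex_f, p1_id, s1_id)
    mo2, fa2 = couple(p2_sex_f, p2_id, s2_id)
    mo_rp, fa_rp = couple(p1_sex_f, p1_id, s1b_id)

    tg1 = np.where(twin1, ids("TG1"), None)
    tg2 = np.where(twin2, ids("TG2"), None)

    add_block(true_, ids("C1a"), sex_c1[0], b1["b1"], mo1, fa1, a_c1[0], c_n1, tg1)
    add_block(true_, ids("C1b"), sex_c1[1], b1["b2"], mo1, fa1, a_c1[1], c_n1, tg1)
    add_block(third1, ids("C1c"), sex_c1[2], b1["b3"], mo1, fa1, a_c1[2], c_n1)
    add_block(true_, ids("C2a"), sex_c2[0], b2["b1"], mo2, fa2, a_c2[0], c_n2, tg2)
    add_block(true_, ids("C2b"), sex_c2[1], b2["b2"], mo2, fa2, a_c2[1], c_n2, tg2)
    add_block(third2, ids("C2c"), sex_c2[2], b2["b3"], mo2, fa2, a_c2[2], c_n2)
    add_block(repart, ids("CRP"), sex_rp, b_rp, mo_rp, fa_rp, a_rp, c_rp)

    persons = pd.concat(blocks, ignore_index=True)
    m = len(persons)

    # --- liability, censoring, diagnosis (fixed draw order) -----------
    persons["E"] = rng.normal(0.0, sd_e, m)
    female = (persons["sex"] == "female").to_numpy()
    liab = persons["A"].to_numpy() + persons["C"].to_numpy() + persons["E"].to_numpy()
    tau = calibrate_threshold(params)
    affected = liab + params.female_liability_shift * female > tau

    birth = persons["birth_year"].to_numpy()
    dies = rng.random(m) < params.death_prob
    death_year = np.where(dies, birth + rng.integers(1, 81, m), np.nan)
    death_year = np.where(death_year > params.study_end, np.nan, death_year)
    emig = rng.random(m) < params.emigration_prob
    emig_year = np.where(emig, birth + rng.integers(1, 61, m), np.nan)
    emig_year = np.where(emig_year > params.study_end, np.nan, emig_year)

    persons["death_year"] = pd.array(death_year, dtype="Int64")
    persons["emigration_year"] = pd.array(emig_year, dtype="Int64")
    persons["born_in_country"] = rng.random(m) >= 0.02
    persons["county"] = np.char.add(
        "C", rng.integers(1, 22, m).astype(str))
    persons["education_gt11"] = rng.random(m) < 0.30

    # observed diagnosis: liability-affected persons whose follow-up window is
    # non-empty get an onset year drawn inside the window
    start = np.maximum(birth, params.study_start).astype(float)
    end = np.minimum.reduce([
        np.full(m, float(params.study_end)),
        np.where(np.isnan(death_year), np.inf, death_year),
        np.where(np.isnan(emig_year), np.inf, emig_year),
    ])
    in_follow = end >= start
    diag = affected & in_follow
    mu = np.log(params.onset_median_age)
    # onset ages drawn for everyone in fixed order; used only where diagnosed
    ages = _truncated_lognormal(rng, mu, params.onset_log_sigma,
                                start - birth, np.where(in_follow, end - birth, start - birth + 1.0))
    event_year = np.clip(birth + np.floor(ages), start, end)

    didx = np.flatnonzero(diag)
    sources = rng.choice(_SOURCE_LEVELS, size=m, p=_SOURCE_PROBS)
    events = pd.DataFrame({
        "person_id": persons["person_id"].to_numpy()[didx],
        "code": SYNCOPE_CODE,
        "event_year": event_year[didx].astype(int),
        "source": sources[didx],
    })

    # repeat syncope events (descriptive only; analysis uses the first)
    rep_u = rng.random(m)
    rep_year_u = rng.random(m)
    rep_mask = diag & (rep_u < params.repeat_event_prob) & (end > event_year)
    ridx = np.flatnonzero(rep_mask)
    if len(ridx):
        ry = event_year[ridx] + np.floor(
            rep_year_u[ridx] * (end[ridx] - event_year[ridx])) + 1
        ry = np.minimum(ry, end[ridx])
        events = pd.concat([events, pd.DataFrame({
            "person_id": persons["person_id"].to_numpy()[ridx],
            "code": SYNCOPE_CODE,
            "event_year": ry.astype(int),
            "source": rng.choice(_SOURCE_LEVELS, size=len(ridx), p=_SOURCE_PROBS),
        })], ignore_index=True)

    # differential TLOC codes for a small fraction of diagnosed persons
    diff_u = rng.random(m)
    diff_mask = diag & (diff_u < params.differential_dx_frac)
    didx2 = np.flatnonzero(diff_mask)
    if len(didx2):
        events = pd.concat([events, pd.DataFrame({
            "person_id": persons["person_id"].to_numpy()[didx2],
            "code": DIFFERENTIAL_CODE,
            "event_year": event_year[didx2].astype(int),
            "source": rng.choice(_SOURCE_LEVELS, size=len(didx2), p=_SOURCE_PROBS),
        })], ignore_index=True)

    events = events.sort_values(["person_id", "event_year", "code"],
                                kind="mergesort").reset_index(drop=True)

    persons["affected_liability"] = affected
    persons = persons[[
        "person_id", "sex", "birth_year", "death_year", "emigration_year",
        "mother_id", "father_id", "born_in_country", "county",
        "education_gt11", "twin_group_id", "A", "C", "E", "affected_liability",
    ]].sort_values("person_id", kind="mergesort").reset_index(drop=True)

    liab_df = persons[["person_id", "A", "C", "E", "affected_liability"]].copy()
    liab_df["liability"] = liab_df["A"] + liab_df["C"] + liab_df["E"]

    zyg_rows = []
    zyg_rows.append(pd.DataFrame({
        "twin_group_id": tg1[twin1], "zygosity": np.where(mz1[twin1], "mz", "dz")}))
    zyg_rows.append(pd.DataFrame({
        "twin_group_id": tg2[twin2], "zygosity": np.where(mz2[twin2], "mz", "dz")}))
    zygosity = pd.concat(zyg_rows, ignore_index=True).sort_values(
        "twin_group_id", kind="mergesort").reset_index(drop=True)

    registry = Registry(
        persons=persons.drop(columns=["A", "C", "E", "affected_liability"]),
        events=events,
    )
    truth = SyntheticTruth(liabilities=liab_df, zygosity=zygosity,
                           threshold=tau, params=params)
    return registry, truth


def simulate_association_rows(
    n_rows: int,
    beta_exposure: float,
    intercept: float = -3.75,
    exposure_prob: float = 0.03,
    beta_by_sex_pair: Optional[Dict[str, float]] = None,
    with_covariates: bool = True,
    seed: int = 0,
) -> pd.DataFrame:
    """Directly generate double-entry-style pair rows from a logistic model
    with a planted exposure effect, for regression parameter-recovery tests.

    Outcome log-odds = intercept + beta*exposure (+ null covariates).  When
    ``beta_by_sex_pair`` maps {'male-male','female-female','opposite'} to
    coefficients, the planted exposure effect differs by sex-pair stratum.
    """
    rng = np.random.default_rng(seed)
    sex_i = np.where(rng.random(n_rows) < 0.5, "female", "male")
    sex_j = np.where(rng.random(n_rows) < 0.5, "female", "male")
    exposure = rng.random(n_rows) < exposure_prob
    beta = np.full(n_rows, beta_exposure)
    if beta_by_sex_pair is not None:
        pair = np.where(sex_i == sex_j,
                        np.char.add(np.char.add(sex_i, "-"), sex_j),
                        "opposite")
        for k, v in beta_by_sex_pair.items():
            beta[pair == k] = v
    logit = intercept + beta * exposure
    y = rng.random(n_rows) < 1.0 / (1.0 + np.exp(-logit))
    out = pd.DataFrame({
        "index_affected": y,
        "relative_affected": exposure,
        "index_sex": sex_i,
        "relative_sex": sex_j,
    })
    if with_covariates:
        out["birth_year"] = rng.integers(1948, 2006, n_rows)
        out["county"] = np.char.add("C", rng.integers(1, 6, n_rows).astype(str))
        out["education_gt11"] = rng.random(n_rows) < 0.3
    return out
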
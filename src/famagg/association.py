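"""Familial-association estimators and the aggregation model object.

Estimators
----------
* incidence rates per 1000 person-years with exact Poisson CIs, and the
  incidence rate ratio between persons with and without an affected relative
* crude (univariate) and covariate-adjusted logistic familial odds ratios,
  fitted on double-entered pair rows
* tetrachoric correlation between relatives' outcomes
* the genetic-resemblance x relative-affected interaction test pooled across
  relationship classes
* sex-pair / age stratification, the Pearson resemblance trend, and the
  sensitivity variants (single entry; exclusion of differential diagnoses)

Model interface
---------------
:class:`FamilialAggregation` bundles the pair rows for one or more
relationship datasets together with each member's outcome and covariates;
``.fit()`` computes every estimator and returns a
:class:`FamilialAggregationResults` whose ``summary()`` renders a table
mirroring a familial-risk report (rates, IRR, crude/adjusted OR, tetrachoric
per relationship).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .pairs import (DoubleEntryTable, RELATIONS, build_all_pairs,
                    cross_tabulate, person_exposure_summary, single_entry)
from .registry import Registry, STUDY_START, STUDY_END, SYNCOPE_CODE, follow_up_table
from .simulate import DIFFERENTIAL_CODE
from .tetrachoric import TetrachoricError, tetrachoric_mle

Z95 = stats.norm.ppf(0.975)

DEFAULT_ADJUST = ("birth_year", "sex", "county", "education")


class EstimationError(ValueError):
    """An estimator's preconditions are not met (degenerate input)."""


class FitError(RuntimeError):
    """A regression failed (separation / non-convergence); carries detail."""


@dataclass(frozen=True)
class FamilialEstimate:
    """One estimate with its 95% CI, measured on the reported scale."""

    measure: str
    value: float
    ci_low: float
    ci_high: float
    se: Optional[float] = None
    stratum: Optional[str] = None
    relation: Optional[str] = None
    n: Optional[float] = None
    p_value: Optional[float] = None
    note: Optional[str] = None

    def rounded(self, ndigits: int = 2) -> Tuple[float, float, float]:
        return (round(self.value, ndigits), round(self.ci_low, ndigits),
                round(self.ci_high, ndigits))


@dataclass(frozen=True)
class ExposureSummary:
    """Person-level counts for one exposure level (relative affected or not)."""

    cases: int
    persons_at_risk: int
    person_years: float

    def __post_init__(self) -> None:
        if self.cases > self.persons_at_risk:
            raise EstimationError("cases cannot exceed persons at risk")


# ---------------------------------------------------------------------------
# Rates


def incidence_rate(cases: float, person_years: float,
                   relation: Optional[str] = None,
                   stratum: Optional[str] = None) -> FamilialEstimate:
    """Events per 1000 person-years with the exact Poisson (gamma) 95% CI."""
    if person_years <= 0:
        raise EstimationError("person_years must be positive")
    rate = 1000.0 * cases / person_years
    if cases > 0:
        lo = stats.chi2.ppf(0.025, 2 * cases) / 2.0
    else:
        lo = 0.0
    hi = stats.chi2.ppf(0.975, 2 * cases + 2) / 2.0
    return FamilialEstimate(
        measure="incidence_rate", value=rate,
        ci_low=1000.0 * lo / person_years, ci_high=1000.0 * hi / person_years,
        relation=relation, stratum=stratum, n=person_years)


def incidence_rate_ratio(exposed: ExposureSummary, unexposed: ExposureSummary,
                         relation: Optional[str] = None) -> FamilialEstimate:
    """Rate in the exposed over rate in the unexposed, log-normal 95% CI."""
    if unexposed.cases == 0:
        raise EstimationError("IRR undefined: zero cases among the unexposed")
    if exposed.person_years <= 0 or unexposed.person_years <= 0:
        raise EstimationError("person_years must be positive in both groups")
    r1 = exposed.cases / exposed.person_years
    r0 = unexposed.cases / unexposed.person_years
    irr = r1 / r0
    if exposed.cases == 0:
        return FamilialEstimate("IRR", 0.0, 0.0, float("nan"),
                                relation=relation, note="zero exposed cases")
    se_log = math.sqrt(1.0 / exposed.cases + 1.0 / unexposed.cases)
    return FamilialEstimate(
        measure="IRR", value=irr,
        ci_low=irr * math.exp(-Z95 * se_log), ci_high=irr * math.exp(Z95 * se_log),
        se=se_log, relation=relation,
        n=exposed.persons_at_risk + unexposed.persons_at_risk)


# ---------------------------------------------------------------------------
# Odds ratios


def crude_or(cases_exposed: float, persons_exposed: float,
             cases_unexposed: float, persons_unexposed: float,
             relation: Optional[str] = None,
             stratum: Optional[str] = None) -> FamilialEstimate:
    """Univariate OR from person-level counts (cases / persons at risk per
    exposure level), with the Woolf 95% CI.

    A zero cell gets the Haldane-Anscombe 0.5 continuity correction, flagged
    in the estimate's note.
    """
    a = cases_exposed
    b = persons_exposed - cases_exposed
    c = cases_unexposed
    d = persons_unexposed - cases_unexposed
    note = None
    if min(a, b, c, d) < 0:
        raise EstimationError("negative cell in OR table")
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        note = "haldane_anscombe_0.5"
        warnings.warn("zero cell in OR table; Haldane-Anscombe correction applied")
    or_ = (a / b) / (c / d)
    se_log = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return FamilialEstimate(
        measure="OR_crude", value=or_,
        ci_low=or_ * math.exp(-Z95 * se_log), ci_high=or_ * math.exp(Z95 * se_log),
        se=se_log, relation=relation, stratum=stratum,
        n=persons_exposed + persons_unexposed, note=note)


def _design_matrix(rows: pd.DataFrame, adjust: Sequence[str]) -> pd.DataFrame:
    """Exposure + requested covariates as a numeric design matrix; constant
    columns (degenerate covariates, e.g. sex in a single-sex subset) are
    dropped rather than breaking the fit."""
    X = pd.DataFrame(index=rows.index)
    X["relative_affected"] = rows["relative_affected"].astype(float)
    for cov in adjust:
        if cov == "birth_year":
            X["birth_year"] = rows["birth_year"].astype(float)
        elif cov == "sex":
            X["sex_female"] = (rows["index_sex"] == "female").astype(float)
        elif cov == "education":
            X["education_gt11"] = rows["education_gt11"].astype(float)
        elif cov == "county":
            dummies = pd.get_dummies(rows["county"], prefix="county",
                                     drop_first=True, dtype=float)
            X = pd.concat([X, dummies], axis=1)
        else:
            raise EstimationError(f"unknown covariate {cov!r}")
    keep = [c for c in X.columns if X[c].nunique() > 1 or c == "relative_affected"]
    return X[keep]


def _fit_logit(y: np.ndarray, X: pd.DataFrame,
               cluster: Optional[np.ndarray] = None):
    Xc = sm.add_constant(X, has_constant="add")
    model = sm.Logit(y.astype(float), Xc.astype(float))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error",
                                  category=sm.tools.sm_exceptions.PerfectSeparationWarning)
            if cluster is not None:
                res = model.fit(disp=0, maxiter=200, cov_type="cluster",
                                cov_kwds={"groups": cluster})
            else:
                res = model.fit(disp=0, maxiter=200)
    except Exception as exc:  # separation, singular matrix, ...
        raise FitError(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", True):
        raise FitError("logistic fit did not converge")
    return res


def _wald_estimate(res, term: str, measure: str, relation=None, stratum=None,
                   n=None) -> FamilialEstimate:
    coef = float(res.params[term])
    se = float(res.bse[term])
    p = float(res.pvalues[term])
    return FamilialEstimate(
        measure=measure, value=math.exp(coef),
        ci_low=math.exp(coef - Z95 * se), ci_high=math.exp(coef + Z95 * se),
        se=se, relation=relation, stratum=stratum, n=n, p_value=p)


def adjusted_or(rows: pd.DataFrame, adjust: Sequence[str] = DEFAULT_ADJUST,
                relation: Optional[str] = None,
                stratum: Optional[str] = None,
                cluster_robust: bool = False) -> FamilialEstimate:
    """Logistic-regression familial OR on double-entered pair rows.

    Outcome = index person's syncope flag; exposure = relative's flag;
    requested covariates belong to the index person.  Wald 95% CI.  With
    ``cluster_robust`` the covariance is clustered on the unordered pair.
    """
    y = rows["index_affected"].to_numpy(dtype=float)
    X = _design_matrix(rows, adjust)
    cluster = None
    if cluster_robust:
        a, b = rows["index_id"].to_numpy(), rows["relative_id"].to_numpy()
        cluster = np.where(a < b, a + "|" + b, b + "|" + a)
    res = _fit_logit(y, X, cluster)
    return _wald_estimate(res, "relative_affected", "OR_adjusted",
                          relation=relation, stratum=stratum, n=len(rows))


def tetrachoric(table: DoubleEntryTable,
                relation: Optional[str] = None) -> FamilialEstimate:
    """Latent bivariate-normal correlation of the double-entry 2x2 table."""
    try:
        rho, se = tetrachoric_mle(table.n11, table.n10, table.n01, table.n00)
    except TetrachoricError as exc:
        raise EstimationError(str(exc)) from exc
    return FamilialEstimate(
        measure="tetrachoric", value=rho,
        ci_low=max(-1.0, rho - Z95 * se) if np.isfinite(se) else float("nan"),
        ci_high=min(1.0, rho + Z95 * se) if np.isfinite(se) else float("nan"),
        se=se, relation=relation, n=table.total)


def resemblance_interaction(rows: pd.DataFrame,
                            adjust: Sequence[str] = (),
                            categorical: bool = False) -> FamilialEstimate:
    """Interaction between genetic resemblance and the relative's status,
    pooled over relationship classes.

    Fits outcome ~ relative_affected + resemblance + relative_affected x
    resemblance (+ covariates); reports the interaction OR per unit
    resemblance.  With ``categorical`` the resemblance main effect enters as
    relationship-class dummies while the interaction stays continuous.
    """
    if rows["relation"].nunique() < 2:
        raise EstimationError(
            "resemblance interaction requires >= 2 relationship classes")
    X = _design_matrix(rows, adjust)
    if categorical:
        dummies = pd.get_dummies(rows["relation"], prefix="relation",
                                 drop_first=True, dtype=float)
        X = pd.concat([X, dummies], axis=1)
    else:
        X["resemblance"] = rows["resemblance"].astype(float)
    X["resemblance_x_affected"] = (rows["resemblance"].to_numpy()
                                   * rows["relative_affected"].to_numpy(dtype=float))
    res = _fit_logit(rows["index_affected"].to_numpy(dtype=float), X)
    return _wald_estimate(res, "resemblance_x_affected", "interaction_OR",
                          n=len(rows))


def pearson_trend(resemblance: Sequence[float],
                  estimates: Sequence[float]) -> FamilialEstimate:
    """Pearson correlation between genetic resemblance and a per-relationship
    estimate (tetrachoric or OR); needs >= 3 points and non-constant input."""
    x = np.asarray(resemblance, dtype=float)
    y = np.asarray(estimates, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise EstimationError("pearson trend needs >= 3 matched points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise EstimationError("pearson trend undefined for constant input")
    r = stats.pearsonr(x, y)
    try:
        ci = r.confidence_interval()
        lo, hi = float(ci.low), float(ci.high)
    except Exception:
        lo = hi = float("nan")
    return FamilialEstimate(measure="pearson_trend", value=float(r.statistic),
                            ci_low=lo, ci_high=hi, p_value=float(r.pvalue),
                            n=len(x))


# ---------------------------------------------------------------------------
# Stratification helpers


def sex_pair_label(index_sex: pd.Series, relative_sex: pd.Series) -> pd.Series:
    lab = np.where(index_sex == relative_sex,
                   np.where(index_sex == "male", "male-male", "female-female"),
                   "opposite-sex")
    return pd.Series(lab, index=index_sex.index)


DEFAULT_AGE_BANDS = ((0, 20), (20, 40), (40, 200))


def age_band_label(age: pd.Series,
                   bands: Sequence[Tuple[int, int]] = DEFAULT_AGE_BANDS) -> pd.Series:
    out = pd.Series("NA", index=age.index, dtype=object)
    for lo, hi in bands:
        name = f"<{hi}" if lo == 0 else (f">={lo}" if hi >= 200 else f"{lo}-{hi - 1}")
        out[(age >= lo) & (age < hi)] = name
    return out


def stratify(rows: pd.DataFrame, by: str, estimator, *,
             age_bands: Sequence[Tuple[int, int]] = DEFAULT_AGE_BANDS,
             **kwargs) -> List[FamilialEstimate]:
    """Run an estimator per stratum of the pair rows.

    ``by`` is ``"sex_pair"`` (male-male / female-female / opposite-sex) or
    ``"age"`` (bands of the index person's age: at first event for cases, at
    end of follow-up otherwise).  A degenerate stratum yields an NA estimate
    rather than raising.
    """
    if by == "sex_pair":
        labels = sex_pair_label(rows["index_sex"], rows["relative_sex"])
    elif by == "age":
        labels = age_band_label(rows["index_age"], age_bands)
    else:
        raise EstimationError(f"unknown stratification {by!r}")
    out: List[FamilialEstimate] = []
    for label in pd.unique(labels):
        sub = rows[labels == label]
        try:
            est = estimator(sub, stratum=str(label), **kwargs)
        except (EstimationError, FitError) as exc:
            est = FamilialEstimate(measure="NA", value=float("nan"),
                                   ci_low=float("nan"), ci_high=float("nan"),
                                   stratum=str(label), n=len(sub),
                                   note=str(exc))
        out.append(est)
    return out


# ---------------------------------------------------------------------------
# Model / Results objects


def _build_pair_rows(registry: Registry, pairs: pd.DataFrame,
                     follow: pd.DataFrame) -> pd.DataFrame:
    """Attach outcomes and index-person covariates to double-entered pairs,
    dropping rows where either member is excluded from follow-up."""
    p = registry.persons.set_index("person_id")
    rows = pairs.copy()
    for side, col in (("index", "index_id"), ("relative", "relative_id")):
        ids = rows[col]
        rows[f"{side}_affected"] = follow["event"].reindex(ids).to_numpy(dtype=bool)
        rows[f"{side}_sex"] = p["sex"].reindex(ids).to_numpy()
        rows[f"{side}_excluded"] = follow["excluded"].reindex(ids).to_numpy(dtype=bool)
    ids = rows["index_id"]
    rows["birth_year"] = p["birth_year"].reindex(ids).to_numpy()
    rows["county"] = p["county"].reindex(ids).to_numpy()
    rows["education_gt11"] = p["education_gt11"].reindex(ids).to_numpy(dtype=bool)
    rows["person_years"] = follow["person_years"].reindex(ids).to_numpy()
    end_year = follow["end_year"].reindex(ids).to_numpy()
    event_year = follow["event_year"].reindex(ids).to_numpy()
    age_ref = np.where(np.isfinite(event_year.astype(float)), event_year, end_year)
    rows["index_age"] = age_ref.astype(float) - rows["birth_year"].astype(float)
    rows = rows[~rows["index_excluded"] & ~rows["relative_excluded"]]
    return rows.drop(columns=["index_excluded", "relative_excluded"]).reset_index(drop=True)


class FamilialAggregation:
    """Familial-aggregation model over double-entered relative-pair rows.

    Parameters
    ----------
    pair_rows:
        One row per double-entered pair with columns index_id, relative_id,
        relation, resemblance, index_affected, relative_affected, index_sex,
        relative_sex, birth_year, county, education_gt11, person_years,
        index_age.  Usually produced by :meth:`from_registry`.
    """

    REQUIRED = ("index_id", "relative_id", "relation", "resemblance",
                "index_affected", "relative_affected")

    def __init__(self, pair_rows: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in pair_rows.columns]
        if missing:
            raise EstimationError(f"pair_rows missing columns: {missing}")
        self.pair_rows = pair_rows.reset_index(drop=True)

    @classmethod
    def from_registry(cls, registry: Registry,
                      pairs: Optional[pd.DataFrame] = None,
                      relations: Iterable[str] = RELATIONS,
                      study_start: int = STUDY_START,
                      study_end: int = STUDY_END,
                      syncope_codes: Iterable[str] = (SYNCOPE_CODE,),
                      **pair_kwargs) -> "FamilialAggregation":
        """Build the model from a registry: resolve follow-up, extract pairs
        (unless given), and attach outcomes and covariates."""
        if pairs is None:
            pairs = build_all_pairs(registry, relations, **pair_kwargs)
        follow = follow_up_table(registry, study_start, study_end, syncope_codes)
        model = cls(_build_pair_rows(registry, pairs, follow))
        model._follow = follow
        model._registry = registry
        return model

    # -- person-level view ---------------------------------------------
    def exposure_summaries(self, relation: str
                           ) -> Tuple[ExposureSummary, ExposureSummary]:
        """(exposed, unexposed) person-level summaries for one relation."""
        rows = self.pair_rows[self.pair_rows["relation"] == relation]
        if not len(rows):
            raise EstimationError(f"no pairs for relation {relation!r}")
        rel_aff = rows["relative_affected"].to_numpy(dtype=bool)
        per = pd.DataFrame({
            "exposed": pd.Series(rel_aff, index=rows["index_id"].to_numpy())
            .groupby(level=0).any()})
        idx = rows.drop_duplicates("index_id").set_index("index_id")
        per["affected"] = idx["index_affected"].reindex(per.index).to_numpy(dtype=bool)
        per["person_years"] = idx["person_years"].reindex(per.index).to_numpy()
        out = []
        for flag in (True, False):
            sub = per[per["exposed"] == flag]
            out.append(ExposureSummary(
                cases=int(sub["affected"].sum()),
                persons_at_risk=int(len(sub)),
                person_years=float(sub["person_years"].sum())))
        return out[0], out[1]

    def fit(self, adjust: Sequence[str] = DEFAULT_ADJUST,
            single_entry_mode: bool = False,
            cluster_robust: bool = False,
            interaction_categorical: bool = False) -> "FamilialAggregationResults":
        """Compute every familial-association estimate.

        ``single_entry_mode`` de-duplicates each unordered pair before the
        regression/tetrachoric steps (sensitivity variant); person-level
        rates are unaffected by entry mode.
        """
        rows = self.pair_rows
        reg_rows = single_entry(rows) if single_entry_mode else rows
        relations = [r for r in RELATIONS if (rows["relation"] == r).any()]
        estimates: List[FamilialEstimate] = []
        tet_by_rel: Dict[str, FamilialEstimate] = {}
        or_by_rel: Dict[str, FamilialEstimate] = {}
        tables: Dict[str, DoubleEntryTable] = {}
        summaries: Dict[str, Tuple[ExposureSummary, ExposureSummary]] = {}
        for rel in relations:
            exp_s, unexp_s = self.exposure_summaries(rel)
            summaries[rel] = (exp_s, unexp_s)
            for label, s in (("affected", exp_s), ("unaffected", unexp_s)):
                if s.person_years > 0:
                    estimates.append(replace(
                        incidence_rate(s.cases, s.person_years, relation=rel),
                        stratum=f"relative_{label}"))
            if exp_s.person_years > 0 and unexp_s.cases > 0:
                estimates.append(incidence_rate_ratio(exp_s, unexp_s, relation=rel))
            try:
                estimates.append(crude_or(
                    exp_s.cases, exp_s.persons_at_risk,
                    unexp_s.cases, unexp_s.persons_at_risk, relation=rel))
            except EstimationError:
                pass
            sub = reg_rows[reg_rows["relation"] == rel]
            full = rows[rows["relation"] == rel]
            table = DoubleEntryTable(
                n11=int((full["index_affected"] & full["relative_affected"]).sum()),
                n10=int((full["index_affected"] & ~full["relative_affected"]).sum()),
                n01=int((~full["index_affected"] & full["relative_affected"]).sum()),
                n00=int((~full["index_affected"] & ~full["relative_affected"]).sum()))
            if single_entry_mode:
                # unordered-pair counts: evenly split discordant cells, which
                # preserves the point estimate and doubles the variance
                table = table.halved()
            tables[rel] = table
            try:
                tet = tetrachoric(table, relation=rel)
                tet_by_rel[rel] = tet
                estimates.append(tet)
            except EstimationError:
                pass
            try:
                adj = adjusted_or(sub, adjust=adjust, relation=rel,
                                  cluster_robust=cluster_robust)
                or_by_rel[rel] = adj
                estimates.append(adj)
            except FitError as exc:
                estimates.append(FamilialEstimate(
                    measure="OR_adjusted", value=float("nan"),
                    ci_low=float("nan"), ci_high=float("nan"),
                    relation=rel, note=str(exc)))

        interaction = None
        if len(relations) >= 2:
            try:
                interaction = resemblance_interaction(
                    reg_rows, adjust=adjust,
                    categorical=interaction_categorical)
                estimates.append(interaction)
            except (EstimationError, FitError) as exc:
                estimates.append(FamilialEstimate(
                    measure="interaction_OR", value=float("nan"),
                    ci_low=float("nan"), ci_high=float("nan"), note=str(exc)))

        trends: Dict[str, FamilialEstimate] = {}
        for name, byrel in (("tetrachoric", tet_by_rel), ("OR_adjusted", or_by_rel)):
            if len(byrel) >= 3:
                g = [float(rows.loc[rows["relation"] == r, "resemblance"].iloc[0])
                     for r in byrel]
                vals = [e.value for e in byrel.values()]
                try:
                    tr = replace(pearson_trend(g, vals),
                                 note=f"resemblance_vs_{name}")
                    trends[name] = tr
                    estimates.append(tr)
                except EstimationError:
                    pass

        return FamilialAggregationResults(
            model=self, estimates=estimates, tables=tables,
            exposure=summaries, interaction=interaction, trends=trends,
            adjust=tuple(adjust), single_entry_mode=single_entry_mode)


@dataclass
class FamilialAggregationResults:
    """Fitted familial-aggregation estimates with a tidy table and summary."""

    model: FamilialAggregation
    estimates: List[FamilialEstimate]
    tables: Dict[str, DoubleEntryTable]
    exposure: Dict[str, Tuple[ExposureSummary, ExposureSummary]]
    interaction: Optional[FamilialEstimate]
    trends: Dict[str, FamilialEstimate]
    adjust: Tuple[str, ...] = DEFAULT_ADJUST
    single_entry_mode: bool = False

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.estimates:
            rows.append({
                "relation": e.relation, "measure": e.measure,
                "stratum": e.stratum, "value": e.value,
                "ci_low": e.ci_low, "ci_high": e.ci_high, "se": e.se,
                "p_value": e.p_value, "n": e.n, "note": e.note})
        return pd.DataFrame(rows)

    def get(self, measure: str, relation: Optional[str] = None,
            stratum: Optional[str] = None) -> FamilialEstimate:
        for e in self.estimates:
            if e.measure == measure and (relation is None or e.relation == relation) \
                    and (stratum is None or e.stratum == stratum):
                return e
        raise KeyError(f"no estimate {measure!r} for relation {relation!r}")

    def summary(self) -> str:
        lines = ["Familial aggregation of syncope",
                 f"adjusted for: {', '.join(self.adjust) or 'nothing (crude)'}"
                 + ("; single-entry" if self.single_entry_mode else "; double-entry"),
                 ""]
        header = (f"{'relation':<14}{'exposure':<12}{'person-yrs':>12}"
                  f"{'cases/at-risk':>16}{'rate/1000py':>24}")
        lines.append(header)
        for rel, (exp_s, unexp_s) in self.exposure.items():
            for label, s in (("unaffected", unexp_s), ("affected", exp_s)):
                try:
                    r = self.get("incidence_rate", rel, f"relative_{label}")
                    rate = f"{r.value:.2f} ({r.ci_low:.2f}-{r.ci_high:.2f})"
                except KeyError:
                    rate = "NA"
                lines.append(f"{rel:<14}{label:<12}{s.person_years:>12.0f}"
                             f"{f'{s.cases}/{s.persons_at_risk}':>16}{rate:>24}")
        lines.append("")
        lines.append(f"{'relation':<14}{'IRR':>20}{'OR crude':>22}"
                     f"{'OR adjusted':>22}{'tetrachoric':>18}")
        for rel in self.exposure:
            cells = []
            for m in ("IRR", "OR_crude", "OR_adjusted"):
                try:
                    e = self.get(m, rel)
                    cells.append(f"{e.value:.2f} ({e.ci_low:.2f}-{e.ci_high:.2f})")
                except KeyError:
                    cells.append("NA")
            try:
                t = self.get("tetrachoric", rel)
                cells.append(f"{t.value:.2f} ({t.se:.2f})")
            except KeyError:
                cells.append("NA")
            lines.append(f"{rel:<14}{cells[0]:>20}{cells[1]:>22}"
                         f"{cells[2]:>22}{cells[3]:>18}")
        if self.interaction is not None:
            e = self.interaction
            lines.append("")
            lines.append(
                f"resemblance x relative-affected interaction OR: "
                f"{e.value:.2f} ({e.ci_low:.2f}-{e.ci_high:.2f}), "
                f"p = {e.p_value:.3g}")
        for name, tr in self.trends.items():
            lines.append(f"Pearson r (resemblance vs {name}): {tr.value:.2f}")
        return "\n".join(lines)

    def stratified(self, by: str, measure: str = "OR_adjusted",
                   **kwargs) -> pd.DataFrame:
        """Per-relationship stratified estimates (sex-pair or age bands)."""
        est = {"OR_adjusted": adjusted_or}.get(measure)
        if est is None:
            raise EstimationError(f"stratification not supported for {measure!r}")
        rows_all = (single_entry(self.model.pair_rows) if self.single_entry_mode
                    else self.model.pair_rows)
        out = []
        for rel in self.exposure:
            sub = rows_all[rows_all["relation"] == rel]
            for e in stratify(sub, by, est, adjust=self.adjust, relation=rel,
                              **kwargs):
                out.append({"relation": rel, "stratum": e.stratum,
                            "measure": e.measure, "value": e.value,
                            "ci_low": e.ci_low, "ci_high": e.ci_high,
                            "p_value": e.p_value, "n": e.n, "note": e.note})
        return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Sensitivity variants


def differential_family_filter(registry: Registry, pairs: pd.DataFrame,
                               codes: Iterable[str] = (DIFFERENTIAL_CODE,)
                               ) -> pd.DataFrame:
    """Drop pairs from families containing any person with a differential
    (non-reflex) TLOC code.  Family = the natal nuclear family of either
    member (parents plus children of the same couple)."""
    codes = set(codes)
    carriers = set(registry.events.loc[registry.events["code"].isin(codes),
                                       "person_id"])
    if not carriers:
        return pairs.reset_index(drop=True)
    p = registry.persons
    has_carrier = p["person_id"].isin(carriers)
    fam_key = p["mother_id"].fillna("") + "\x00" + p["father_id"].fillna("")
    fam_bad = has_carrier.groupby(fam_key.to_numpy()).transform("any")
    parent_carrier = (p["mother_id"].isin(carriers) | p["father_id"].isin(carriers))
    person_bad = pd.Series(
        (has_carrier | fam_bad | parent_carrier).to_numpy(),
        index=p["person_id"])
    bad_i = person_bad.reindex(pairs["index_id"]).to_numpy(dtype=bool)
    bad_r = person_bad.reindex(pairs["relative_id"]).to_numpy(dtype=bool)
    return pairs[~(bad_i | bad_r)].reset_index(drop=True)


def sensitivity_filters(registry: Registry, pairs: pd.DataFrame, mode: str,
                        adjust: Sequence[str] = DEFAULT_ADJUST,
                        **fit_kwargs) -> Tuple["FamilialAggregationResults", pd.DataFrame]:
    """Re-run the estimates under a sensitivity variant and report deltas.

    ``mode``: ``exclude_differential_dx`` drops families carrying differential
    TLOC codes; ``single_entry`` de-duplicates ordered pairs.  The delta
    report compares each (relation, measure) estimate with the baseline fit.
    """
    base = FamilialAggregation.from_registry(registry, pairs=pairs).fit(
        adjust=adjust, **fit_kwargs)
    if mode == "exclude_differential_dx":
        filtered = differential_family_filter(registry, pairs)
        variant = FamilialAggregation.from_registry(registry, pairs=filtered).fit(
            adjust=adjust, **fit_kwargs)
    elif mode == "single_entry":
        variant = FamilialAggregation.from_registry(registry, pairs=pairs).fit(
            adjust=adjust, single_entry_mode=True, **fit_kwargs)
    else:
        raise EstimationError(f"unknown sensitivity mode {mode!r}")
    b = base.to_frame().set_index(["relation", "measure", "stratum"])
    v = variant.to_frame().set_index(["relation", "measure", "stratum"])
    joined = b[["value", "ci_low", "ci_high"]].join(
        v[["value", "ci_low", "ci_high"]], lsuffix="_base", rsuffix="_variant",
        how="outer")
    joined["delta"] = joined["value_variant"] - joined["value_base"]
    return variant, joined.reset_index()
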
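"""Person-registry data model and delimited-text I/O.

The analysis consumes two tables: a person table (one row per registered
individual, with parent links that encode the multigeneration pedigree) and a
diagnosis table (one row per coded health-care contact).  Both are plain
delimited text (tab or comma, auto-detected) with a header row; missing
optional fields are encoded as the empty string.

Follow-up is resolved at whole-year granularity.  A person's follow-up window
opens at the study start (or their birth year, whichever is later) and closes
at the first syncope diagnosis, death, emigration, or the administrative end
of the study, whichever comes first.  Persons whose window closes before it
opens (for example, death before the study start) are flagged excluded rather
than raising an error, mirroring the cohort's exclusion rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

#: ICD-style code used as the proxy for reflex syncope.
SYNCOPE_CODE = "R559"

#: Default administrative follow-up window (years, inclusive start/end).
STUDY_START = 1997
STUDY_END = 2015

PERSON_COLUMNS = [
    "person_id",
    "sex",
    "birth_year",
    "death_year",
    "emigration_year",
    "mother_id",
    "father_id",
    "born_in_country",
    "county",
    "education_gt11",
    "twin_group_id",
]

DIAGNOSIS_COLUMNS = ["person_id", "code", "event_year", "source"]

_SEXES = frozenset({"male", "female"})
_SOURCES = frozenset({"primary_care", "inpatient", "outpatient"})


class RegistryError(ValueError):
    """Base error for registry parsing/validation problems."""


class RegistryParseError(RegistryError):
    """A file row could not be parsed; the message names the offending line."""


class RegistryValidationError(RegistryError):
    """The parsed tables violate a registry invariant (e.g. duplicate ids)."""


@dataclass(frozen=True)
class PersonRecord:
    """One registry row: identity, sex, parent links, vital years, covariates."""

    person_id: str
    sex: str
    birth_year: int
    death_year: Optional[int] = None
    emigration_year: Optional[int] = None
    mother_id: Optional[str] = None
    father_id: Optional[str] = None
    born_in_country: bool = True
    county: str = "01"
    education_gt11: bool = False
    twin_group_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.sex not in _SEXES:
            raise RegistryValidationError(f"sex must be male/female, got {self.sex!r}")
        for name in ("death_year", "emigration_year"):
            y = getattr(self, name)
            if y is not None and y < self.birth_year:
                raise RegistryValidationError(
                    f"{name}={y} precedes birth_year={self.birth_year} "
                    f"for person {self.person_id}"
                )


@dataclass(frozen=True)
class DiagnosisEvent:
    """A coded diagnosis with calendar year and source register."""

    person_id: str
    code: str
    event_year: int
    source: str = "primary_care"


@dataclass(frozen=True)
class FollowUpWindow:
    """Resolved follow-up for one person.

    ``excluded`` marks persons whose window is empty (e.g. died before the
    study start); such persons contribute no person-time and no events.
    """

    start_year: int
    end_year: int
    event: bool
    event_year: Optional[int] = None
    excluded: bool = False

    @property
    def person_years(self) -> float:
        """Exposure time in years; events in the opening year carry 0.5 years
        so that no observed event has zero exposure."""
        if self.excluded:
            return 0.0
        py = float(self.end_year - self.start_year)
        if self.event and py == 0.0:
            py = 0.5
        return py


@dataclass
class Registry:
    """Validated person + diagnosis tables.

    ``persons`` is indexed positionally with a ``person_id`` column;
    ``events`` carries one row per diagnosis.  ``orphan_events`` holds any
    diagnosis rows whose person id is absent from the person table (reported,
    not silently dropped).
    """

    persons: pd.DataFrame
    events: pd.DataFrame
    orphan_events: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=DIAGNOSIS_COLUMNS))

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        p = self.persons
        missing = [c for c in PERSON_COLUMNS if c not in p.columns]
        if missing:
            raise RegistryValidationError(f"person table missing columns: {missing}")
        dup = p["person_id"][p["person_id"].duplicated()]
        if len(dup):
            raise RegistryValidationError(
                f"duplicate person_id values: {sorted(set(dup))[:5]}"
            )
        bad_sex = set(p["sex"].unique()) - _SEXES
        if bad_sex:
            raise RegistryValidationError(f"unknown sex values: {sorted(bad_sex)}")
        for col in ("death_year", "emigration_year"):
            vals = p[col]
            bad = vals.notna() & (vals < p["birth_year"])
            if bad.any():
                who = p.loc[bad, "person_id"].iloc[0]
                raise RegistryValidationError(
                    f"{col} precedes birth_year for person {who}"
                )
        # co-twins share both parents and birth year
        twins = p[p["twin_group_id"].notna()]
        if len(twins):
            g = twins.groupby("twin_group_id", sort=False)
            for col in ("mother_id", "father_id", "birth_year"):
                n_distinct = g[col].nunique(dropna=False)
                if (n_distinct > 1).any():
                    gid = n_distinct[n_distinct > 1].index[0]
                    raise RegistryValidationError(
                        f"co-twins in group {gid} differ in {col}"
                    )
        ev = self.events
        missing = [c for c in DIAGNOSIS_COLUMNS if c not in ev.columns]
        if missing:
            raise RegistryValidationError(f"diagnosis table missing columns: {missing}")
        if len(ev):
            birth = p.set_index("person_id")["birth_year"]
            known = ev["person_id"].isin(birth.index)
            orphans = ev[~known]
            if len(orphans):
                self.orphan_events = orphans.reset_index(drop=True)
                self.events = ev[known].reset_index(drop=True)
                ev = self.events
            if len(ev):
                b = birth.reindex(ev["person_id"]).to_numpy()
                early = ev["event_year"].to_numpy() < b
                if early.any():
                    who = ev.loc[np.flatnonzero(early)[0], "person_id"]
                    raise RegistryValidationError(
                        f"event_year precedes birth_year for person {who}"
                    )

    # -- convenience ----------------------------------------------------
    def person_records(self) -> Iterable[PersonRecord]:
        for row in self.persons.itertuples(index=False):
            yield PersonRecord(
                person_id=row.person_id,
                sex=row.sex,
                birth_year=int(row.birth_year),
                death_year=None if pd.isna(row.death_year) else int(row.death_year),
                emigration_year=None if pd.isna(row.emigration_year) else int(row.emigration_year),
                mother_id=None if pd.isna(row.mother_id) else row.mother_id,
                father_id=None if pd.isna(row.father_id) else row.father_id,
                born_in_country=bool(row.born_in_country),
                county=row.county,
                education_gt11=bool(row.education_gt11),
                twin_group_id=None if pd.isna(row.twin_group_id) else row.twin_group_id,
            )

    def events_for(self, person_id: str) -> pd.DataFrame:
        return self.events[self.events["person_id"] == person_id]


# ---------------------------------------------------------------------------
# I/O


def _read_table(path, columns: Sequence[str], int_cols: Sequence[str],
                opt_int_cols: Sequence[str], bool_cols: Sequence[str]) -> pd.DataFrame:
    """Read a delimited text table, auto-detecting tab vs comma, with typed
    columns and parse errors that name the offending line."""
    df = pd.read_csv(
        path,
        sep=None,
        engine="python",
        dtype=str,
        keep_default_na=False,
        na_values=[],
    )
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise RegistryParseError(f"{path}: missing columns {missing}")
    df = df[list(columns)]
    df = df.replace({"": None})

    def _to_int(col: str, optional: bool) -> pd.Series:
        raw = df[col]
        out = pd.to_numeric(raw, errors="coerce")
        bad = out.isna() & raw.notna()
        if (not optional) and (out.isna().any()):
            bad = out.isna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is line 1
            raise RegistryParseError(
                f"{path}: line {line}: cannot parse {col!r} value {raw[bad].iloc[0]!r}"
            )
        return out.astype("Int64")

    for col in int_cols:
        df[col] = _to_int(col, optional=False).astype("int64")
    for col in opt_int_cols:
        df[col] = _to_int(col, optional=True)
    for col in bool_cols:
        mapped = df[col].map({"1": True, "0": False, "true": True, "false": False,
                              "True": True, "False": False})
        bad = mapped.isna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise RegistryParseError(
                f"{path}: line {line}: cannot parse boolean {col!r} value "
                f"{df[col][bad].iloc[0]!r}"
            )
        df[col] = mapped.astype(bool)
    return df


def read_registry(person_file, diagnosis_file) -> Registry:
    """Read and validate a registry from persons.tsv + diagnoses.tsv."""
    persons = _read_table(
        person_file,
        PERSON_COLUMNS,
        int_cols=["birth_year"],
        opt_int_cols=["death_year", "emigration_year"],
        bool_cols=["born_in_country", "education_gt11"],
    )
    events = _read_table(
        diagnosis_file,
        DIAGNOSIS_COLUMNS,
        int_cols=["event_year"],
        opt_int_cols=[],
        bool_cols=[],
    )
    return Registry(persons=persons, events=events)


def write_registry(registry: Registry, person_file, diagnosis_file) -> None:
    """Write a registry back to delimited text (tab-separated, empty string
    for missing optional fields)."""
    p = registry.persons.copy()
    for col in ("born_in_country", "education_gt11"):
        p[col] = p[col].map({True: "1", False: "0"})
    p.to_csv(person_file, sep="\t", index=False, na_rep="")
    registry.events.to_csv(diagnosis_file, sep="\t", index=False, na_rep="")


# ---------------------------------------------------------------------------
# Follow-up


def follow_up(
    person: PersonRecord,
    events: Sequence[DiagnosisEvent],
    study_start: int = STUDY_START,
    study_end: int = STUDY_END,
    syncope_codes: Iterable[str] = (SYNCOPE_CODE,),
) -> FollowUpWindow:
    """Resolve one person's follow-up window.

    Start = max(birth, study start).  End = min(first syncope event, death,
    emigration, study end).  The event flag is set when the first syncope
    event falls inside the window; an event before the window start empties
    the window and excludes the person (prevalent case).
    """
    codes = set(syncope_codes)
    years = sorted(e.event_year for e in events
                   if e.person_id == person.person_id and e.code in codes)
    first = years[0] if years else None
    start = max(person.birth_year, study_start)
    candidates = [study_end]
    if person.death_year is not None:
        candidates.append(person.death_year)
    if person.emigration_year is not None:
        candidates.append(person.emigration_year)
    if first is not None:
        candidates.append(first)
    end = min(candidates)
    if end < start:
        return FollowUpWindow(start, start, event=False, excluded=True)
    event = first is not None and start <= first <= end
    return FollowUpWindow(start, end, event=event,
                          event_year=first if event else None)


def follow_up_table(
    registry: Registry,
    study_start: int = STUDY_START,
    study_end: int = STUDY_END,
    syncope_codes: Iterable[str] = (SYNCOPE_CODE,),
) -> pd.DataFrame:
    """Vectorised :func:`follow_up` over a whole registry.

    Returns one row per person: start, end, event, event_year, person_years,
    excluded.  Indexed by person_id.
    """
    p = registry.persons
    ev = registry.events
    ev = ev[ev["code"].isin(set(syncope_codes))]
    first = ev.groupby("person_id")["event_year"].min()

    out = pd.DataFrame(index=p["person_id"])
    birth = p["birth_year"].to_numpy(dtype=float)
    start = np.maximum(birth, study_start)
    death = p["death_year"].to_numpy(dtype=float, na_value=np.inf)
    emig = p["emigration_year"].to_numpy(dtype=float, na_value=np.inf)
    fy = first.reindex(p["person_id"]).to_numpy(dtype=float, na_value=np.inf)
    end = np.minimum.reduce([np.full_like(birth, float(study_end)), death, emig, fy])
    excluded = end < start
    event = (~excluded) & np.isfinite(fy) & (fy >= start) & (fy <= end)
    py = np.where(excluded, 0.0, end - start)
    py = np.where(event & (py == 0.0), 0.5, py)

    out["start_year"] = start.astype(int)
    out["end_year"] = np.where(excluded, start, end).astype(int)
    out["event"] = event
    out["event_year"] = np.where(event, fy, np.nan)
    out["person_years"] = py
    out["excluded"] = excluded
    return out
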
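import numpy as np
import pandas as pd
import pytest

from famagg.registry import DIAGNOSIS_COLUMNS, PERSON_COLUMNS, Registry


def make_persons(rows):
    """Build a person table from (person_id, sex, birth, death, emig, mother,
    father, twin_group) tuples with sensible covariate defaults."""
    recs = []
    for r in rows:
        pid, sex, birth, death, emig, mother, father, twin = r
        recs.append({
            "person_id": pid, "sex": sex, "birth_year": birth,
            "death_year": death, "emigration_year": emig,
            "mother_id": mother, "father_id": father,
            "born_in_country": True, "county": "C1",
            "education_gt11": False, "twin_group_id": twin,
        })
    df = pd.DataFrame(recs, columns=PERSON_COLUMNS)
    for col in ("death_year", "emigration_year"):
        df[col] = pd.array(df[col], dtype="Int64")
    return df


def make_events(rows):
    return pd.DataFrame(
        [dict(zip(DIAGNOSIS_COLUMNS, r)) for r in rows],
        columns=DIAGNOSIS_COLUMNS)


@pytest.fixture
def three_person_registry():
    persons = make_persons([
        ("a", "female", 1980, None, None, None, None, None),
        ("b", "male", 1985, None, None, None, None, None),
        ("c", "female", 1990, None, None, None, None, None),
    ])
    events = make_events([("b", "R559", 2005, "primary_care")])
    return Registry(persons=persons, events=events)


@pytest.fixture
def pedigree_registry():
    """Three-generation, 14-person pedigree containing every relationship:
    a twin pair (t1,t2), a sibship of three (c1-c3), a half-sibling (h1),
    and two sets of cousins across the two nuclear families."""
    persons = make_persons([
        ("g1", "male", 1935, None, None, None, None, None),
        ("g2", "female", 1938, None, None, None, None, None),
        ("p1", "male", 1960, None, None, "g2", "g1", None),
        ("p2", "female", 1962, None, None, "g2", "g1", None),
        ("q1", "female", 1961, None, None, None, None, None),
        ("q2", "male", 1963, None, None, None, None, None),
        ("q3", "female", 1965, None, None, None, None, None),
        ("c1", "male", 1985, None, None, "q1", "p1", None),
        ("c2", "female", 1988, None, None, "q1", "p1", None),
        ("c3", "male", 1990, None, None, "q1", "p1", None),
        ("h1", "female", 1995, None, None, "q3", "p1", None),
        ("d1", "male", 1992, None, None, "p2", "q2", None),
        ("t1", "female", 1998, None, None, "p2", "q2", "TG1"),
        ("t2", "female", 1998, None, None, "p2", "q2", "TG1"),
    ])
    events = make_events([
        ("c1", "R559", 2003, "primary_care"),
        ("t1", "R559", 2010, "outpatient"),
    ])
    return Registry(persons=persons, events=events)
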
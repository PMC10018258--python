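"""Shared fixtures: one deterministic cohort, its package, and its resources.

Session scope keeps the suite fast — the cohort and transform output are
immutable, so tests must not mutate them in place (copy first).
"""

import pandas as pd
import pytest

import mimic_fhir as mf
from mimic_fhir.profiles import package_from_terminology


@pytest.fixture(scope="session")
def cohort_config() -> mf.CohortConfig:
    return mf.CohortConfig(n_patients=20, seed=7)


@pytest.fixture(scope="session")
def db(cohort_config) -> mf.SourceDatabase:
    return mf.generate_cohort(cohort_config)


@pytest.fixture(scope="session")
def pkg(db) -> mf.ConformancePackage:
    return package_from_terminology(db.terminology)


@pytest.fixture(scope="session")
def transformed(db, pkg):
    return mf.transform_cohort(db, pkg)


@pytest.fixture(scope="session")
def resources(transformed):
    return transformed[0]


@pytest.fixture(scope="session")
def report(transformed):
    return transformed[1]


@pytest.fixture(scope="session")
def bundled(resources):
    return mf.bundle_cohort(resources)


def make_micro_db(rows: list[dict]) -> mf.SourceDatabase:
    """A one-patient database whose microbiology table is exactly ``rows``.

    Rows need only microbiology-specific fields; subject/admission keys are
    filled in from the host cohort.
    """
    base = mf.generate_cohort(mf.CohortConfig(n_patients=1, seed=5)).copy()
    adm = base.tables["admissions"].iloc[0]
    full = []
    for i, row in enumerate(rows):
        full.append({
            "microevent_id": 1000 + i,
            "subject_id": int(adm["subject_id"]),
            "hadm_id": int(adm["hadm_id"]),
            "charttime": str(adm["admittime"]),
            **row,
        })
    schema = mf.synthetic_source.TABLE_SCHEMAS["microbiologyevents"]
    df = pd.DataFrame(full, columns=list(schema))
    for col, kind in schema.items():
        df[col] = df[col].astype({"int": "Int64", "float": "float64", "str": "string"}[kind])
    base.tables["microbiologyevents"] = df
    return base
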
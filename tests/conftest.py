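import sqlite3

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fedomop import copd_demo, generate_cdm, partition_sites

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


TINY_DDL = [
    "CREATE TABLE person (person_id INTEGER PRIMARY KEY, gender_concept_id INTEGER, year_of_birth INTEGER)",
    "CREATE TABLE provider (provider_id INTEGER PRIMARY KEY, provider_name TEXT)",
    "CREATE TABLE visit_occurrence (visit_occurrence_id INTEGER PRIMARY KEY, person_id INTEGER, provider_id INTEGER, visit_start_date TEXT)",
    "CREATE TABLE condition_occurrence (condition_occurrence_id INTEGER PRIMARY KEY, person_id INTEGER, condition_concept_id INTEGER, condition_start_date TEXT)",
    "CREATE TABLE measurement (measurement_id INTEGER PRIMARY KEY, person_id INTEGER, measurement_concept_id INTEGER, visit_occurrence_id INTEGER, measurement_date TEXT, value_as_number REAL, value_as_concept_id INTEGER)",
    "CREATE TABLE concept (concept_id INTEGER PRIMARY KEY, concept_name TEXT, domain_id TEXT, vocabulary_id TEXT)",
    "CREATE TABLE site_notes (note_id INTEGER PRIMARY KEY, person_id INTEGER, txt TEXT)",
    "CREATE TABLE standalone (code TEXT)",
]


def build_tiny_db(path=":memory:", n_persons=20, n_events=500, seed=42):
    """Small mixed-schema CDM-ish database for schema/query tests."""
    rng = np.random.default_rng(seed)
    conn = sqlite3.connect(path)
    for ddl in TINY_DDL:
        conn.execute(ddl)
    conn.executemany(
        "INSERT INTO person VALUES (?, ?, ?)",
        [(p, 9000 + int(rng.integers(0, 2)), 1950 + int(rng.integers(0, 50))) for p in range(1, n_persons + 1)],
    )
    conn.executemany("INSERT INTO provider VALUES (?, ?)", [(1, "A"), (2, "B")])
    conn.executemany(
        "INSERT INTO visit_occurrence VALUES (?, ?, ?, ?)",
        [
            (v, int(rng.integers(1, n_persons + 1)), int(rng.integers(1, 3)), "2019-05-01")
            for v in range(1, 51)
        ],
    )
    concepts = [3004249, 317009, 9191, 3024561]
    conn.executemany(
        "INSERT INTO concept VALUES (?, ?, ?, ?)",
        [
            (3004249, "Systolic blood pressure", "Measurement", "LOINC"),
            (317009, "Asthma", "Condition", "SNOMED"),
            (9191, "Positive", "Meas Value", "SNOMED"),
            (3024561, "Hemoglobin", "Measurement", "LOINC"),
        ],
    )
    meas = []
    for m in range(1, n_events + 1):
        meas.append(
            (
                m,
                int(rng.integers(1, n_persons + 1)),
                int(rng.choice(concepts)),
                int(rng.integers(1, 51)),
                f"20{int(rng.integers(15, 21))}-0{int(rng.integers(1, 10))}-15",
                round(float(rng.normal(100, 15)), 1),
                None,
            )
        )
    conn.executemany("INSERT INTO measurement VALUES (?, ?, ?, ?, ?, ?, ?)", meas)
    conn.executemany(
        "INSERT INTO condition_occurrence VALUES (?, ?, ?, ?)",
        [
            (c, int(rng.integers(1, n_persons + 1)), 317009, "2018-03-01")
            for c in range(1, 40)
        ],
    )
    conn.executemany(
        "INSERT INTO site_notes VALUES (?, ?, ?)",
        [(1, 3, "note a"), (2, 5, "note b")],
    )
    conn.execute("INSERT INTO standalone VALUES ('x')")
    conn.commit()
    return conn


@pytest.fixture
def tiny_conn():
    conn = build_tiny_db()
    yield conn
    conn.close()


@pytest.fixture(scope="session")
def copd_run(tmp_path_factory):
    """One 20,000-person COPD scenario, merged plus a 3-site partition."""
    root = tmp_path_factory.mktemp("copd")
    config = copd_demo(n_persons=20_000, seed=11, n_sites=3)
    merged = generate_cdm(config, str(root / "merged.db"))
    site_paths = partition_sites(merged, 3, seed=11)
    return {"config": config, "merged": merged, "sites": site_paths}


COPD_PREDICTORS = (
    "tobacco_use",
    "vitamin_d_deficiency",
    "history_of_asthma",
    "history_of_rheumatoid_arthritis",
)
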
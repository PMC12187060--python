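"""Synthetic OMOP-CDM databases with known ground truth.

Generates single-file SQLite databases shaped like an OMOP CDM v5.3 extract:
a ``person`` demographics table, multi-record domain tables
(``condition_occurrence``, ``observation``, ``measurement``) keyed by
``*_concept_id`` columns, and a ``concept`` vocabulary table.  Every
predictor is an independent Bernoulli indicator at a stated prevalence, and
the binary outcome follows the stated logistic model over those indicators —
so the generating log-odds-ratios are the exact estimand of a correctly
specified logistic regression, which makes recovery tests unambiguous.

The default scenario, ``copd_demo``, is a COPD cohort with four binary
predictors (tobacco use, vitamin D deficiency, history of asthma, history of
rheumatoid arthritis) whose generating odds ratios are calibrated to 6.43,
6.14, 20.02 and 8.22.

Longitudinal structure: repeated haemoglobin measurements on a fixed annual
grid with missing-at-random dropout, plus a SARS-COV2 antigen test whose
value is the vocabulary concept 9191 ("Positive") or a local "Negative"
concept.  Local concepts use ids ≥ 2,000,000,000, OMOP's conventional range
for site-defined concepts.

:func:`partition_sites` splits a generated database into per-site databases
by shuffling persons and dealing them round-robin; every event row follows
its person and the vocabulary is replicated to every site.
"""

from __future__ import annotations

import os
import sqlite3
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = [
    "PredictorSpec",
    "OutcomeSpec",
    "LongitudinalSpec",
    "SynthConfig",
    "copd_demo",
    "simulate_cohort",
    "generate_cdm",
    "partition_sites",
]

#: vocabulary concept for a positive qualitative test result
POSITIVE_CONCEPT_ID = 9191

_LOCAL_BASE = 2_000_000_000


@dataclass(frozen=True)
class PredictorSpec:
    """One binary predictor: a concept a person either carries or not."""

    concept_id: int
    name: str
    table: str  # domain table holding the event ("condition_occurrence" | "observation")
    prevalence: float

    def __post_init__(self) -> None:
        if not (0.0 < self.prevalence < 1.0):
            raise ConfigurationError(
                f"prevalence of '{self.name}' must be in (0, 1), got {self.prevalence}"
            )
        if self.table not in ("condition_occurrence", "observation"):
            raise ConfigurationError(
                f"predictor table must be condition_occurrence or observation, got '{self.table}'"
            )


@dataclass(frozen=True)
class OutcomeSpec:
    """The binary outcome and its generating logistic model."""

    concept_id: int
    name: str
    intercept: float
    log_odds_ratios: tuple[float, ...]


@dataclass(frozen=True)
class LongitudinalSpec:
    """Repeated numeric measurements on a shared annual time grid."""

    concept_id: int
    name: str
    n_time_points: int = 3
    missing_rate: float = 0.2
    mean: float = 13.5
    sd: float = 1.5

    def __post_init__(self) -> None:
        if self.n_time_points < 1:
            raise ConfigurationError("n_time_points must be >= 1")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigurationError("missing_rate must be in [0, 1)")


@dataclass(frozen=True)
class SynthConfig:
    n_persons: int
    seed: int
    predictors: tuple[PredictorSpec, ...]
    outcome: OutcomeSpec
    longitudinal: Optional[LongitudinalSpec] = None
    n_sites: int = 1

    def __post_init__(self) -> None:
        if self.n_persons < 1:
            raise ConfigurationError("n_persons must be >= 1")
        if self.n_sites < 1:
            raise ConfigurationError("n_sites must be >= 1")
        if self.n_sites > self.n_persons:
            raise ConfigurationError("n_sites cannot exceed n_persons")
        if len(self.outcome.log_odds_ratios) != len(self.predictors):
            raise ConfigurationError(
                "outcome needs one log-odds-ratio per predictor "
                f"({len(self.predictors)} predictors, "
                f"{len(self.outcome.log_odds_ratios)} log-ORs)"
            )
        ids = [p.concept_id for p in self.predictors] + [self.outcome.concept_id]
        if self.longitudinal is not None:
            ids.append(self.longitudinal.concept_id)
        if len(set(ids)) != len(ids):
            raise ConfigurationError("concept ids must be unique across the scenario")


def copd_demo(n_persons: int = 20_000, seed: int = 0, n_sites: int = 3) -> SynthConfig:
    """The default calibration scenario: a COPD cohort.

    Predictor prevalences are field-realistic EHR values (tobacco use 0.25,
    vitamin D deficiency 0.10, asthma history 0.08, rheumatoid arthritis
    history 0.04); generating odds ratios are 6.43, 6.14, 20.02 and 8.22
    with baseline log-odds −4.
    """
    predictors = (
        PredictorSpec(_LOCAL_BASE + 1, "Tobacco use", "observation", 0.25),
        PredictorSpec(_LOCAL_BASE + 2, "Vitamin D deficiency", "condition_occurrence", 0.10),
        PredictorSpec(_LOCAL_BASE + 3, "History of asthma", "condition_occurrence", 0.08),
        PredictorSpec(
            _LOCAL_BASE + 4, "History of rheumatoid arthritis", "condition_occurrence", 0.04
        ),
    )
    outcome = OutcomeSpec(
        concept_id=_LOCAL_BASE + 10,
        name="COPD",
        intercept=-4.0,
        log_odds_ratios=(
            float(np.log(6.43)),
            float(np.log(6.14)),
            float(np.log(20.02)),
            float(np.log(8.22)),
        ),
    )
    longitudinal = LongitudinalSpec(concept_id=_LOCAL_BASE + 5, name="Hemoglobin")
    return SynthConfig(
        n_persons=n_persons,
        seed=seed,
        predictors=predictors,
        outcome=outcome,
        longitudinal=longitudinal,
        n_sites=n_sites,
    )


def simulate_cohort(config: SynthConfig, rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Draw the ground-truth cohort matrix: person_id, one 0/1 column per
    predictor (named by sanitized concept name), and the 0/1 outcome."""
    from .transform import sanitize_identifier

    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_persons
    data = {"person_id": np.arange(1, n + 1)}
    eta = np.full(n, config.outcome.intercept, dtype=float)
    for pred, beta in zip(config.predictors, config.outcome.log_odds_ratios):
        x = (rng.random(n) < pred.prevalence).astype(int)
        data[sanitize_identifier(pred.name)] = x
        eta += beta * x
    prob = 1.0 / (1.0 + np.exp(-eta))
    data[sanitize_identifier(config.outcome.name)] = (rng.random(n) < prob).astype(int)
    return pd.DataFrame(data)


_SCHEMA_SQL = {
    "person": (
        "CREATE TABLE person ("
        "person_id INTEGER PRIMARY KEY, gender_concept_id INTEGER, "
        "year_of_birth INTEGER)"
    ),
    "condition_occurrence": (
        "CREATE TABLE condition_occurrence ("
        "condition_occurrence_id INTEGER PRIMARY KEY, person_id INTEGER, "
        "condition_concept_id INTEGER, condition_start_date TEXT)"
    ),
    "observation": (
        "CREATE TABLE observation ("
        "observation_id INTEGER PRIMARY KEY, person_id INTEGER, "
        "observation_concept_id INTEGER, observation_date TEXT)"
    ),
    "measurement": (
        "CREATE TABLE measurement ("
        "measurement_id INTEGER PRIMARY KEY, person_id INTEGER, "
        "measurement_concept_id INTEGER, measurement_date TEXT, "
        "value_as_number REAL, value_as_concept_id INTEGER)"
    ),
    "concept": (
        "CREATE TABLE concept ("
        "concept_id INTEGER PRIMARY KEY, concept_name TEXT, "
        "domain_id TEXT, vocabulary_id TEXT)"
    ),
}

#: fixed annual measurement grid (mid-January each year, starting 2016)
_GRID_START_YEAR = 2016


def _random_date(rng: np.random.Generator) -> str:
    """Uniform date over 2015–2020 as ISO text."""
    start = np.datetime64("2015-01-01")
    span = int((np.datetime64("2020-12-31") - start).astype(int)) + 1
    return str(start + np.timedelta64(int(rng.integers(0, span)), "D"))


def generate_cdm(config: SynthConfig, destination: str) -> str:
    """Write one synthetic CDM database to ``destination``; returns the path.

    Deterministic: the same config (seed included) always produces the same
    table contents.  The config is validated (at construction) before any
    write happens.
    """
    rng = np.random.default_rng(config.seed)
    cohort = simulate_cohort(config, rng)
    from .transform import sanitize_identifier

    if os.path.exists(destination):
        os.remove(destination)
    conn = sqlite3.connect(destination)
    try:
        for sql in _SCHEMA_SQL.values():
            conn.execute(sql)

        # --- vocabulary -------------------------------------------------
        concepts = [
            (POSITIVE_CONCEPT_ID, "Positive", "Meas Value", "SNOMED"),
            (_LOCAL_BASE + 6, "Negative", "Meas Value", "Local"),
            (_LOCAL_BASE + 7, "SARS-COV2 (antigen)", "Measurement", "Local"),
            (_LOCAL_BASE + 8, "MALE", "Gender", "Local"),
            (_LOCAL_BASE + 9, "FEMALE", "Gender", "Local"),
        ]
        for pred in config.predictors:
            domain = "Condition" if pred.table == "condition_occurrence" else "Observation"
            concepts.append((pred.concept_id, pred.name, domain, "Local"))
        concepts.append((config.outcome.concept_id, config.outcome.name, "Condition", "Local"))
        if config.longitudinal is not None:
            concepts.append(
                (config.longitudinal.concept_id, config.longitudinal.name, "Measurement", "Local")
            )
        conn.executemany("INSERT INTO concept VALUES (?, ?, ?, ?)", sorted(concepts))

        # --- person ------------------------------------------------------
        n = config.n_persons
        genders = np.where(rng.random(n) < 0.5, _LOCAL_BASE + 8, _LOCAL_BASE + 9)
        births = rng.integers(1940, 2001, size=n)
        conn.executemany(
            "INSERT INTO person VALUES (?, ?, ?)",
            [
                (int(pid), int(g), int(b))
                for pid, g, b in zip(cohort["person_id"], genders, births)
            ],
        )

        # --- predictor and outcome events -------------------------------
        cond_rows: list[tuple] = []
        obs_rows: list[tuple] = []
        for pred in config.predictors:
            col = sanitize_identifier(pred.name)
            for pid in cohort.loc[cohort[col] == 1, "person_id"]:
                row = (int(pid), pred.concept_id, _random_date(rng))
                if pred.table == "condition_occurrence":
                    cond_rows.append(row)
                else:
                    obs_rows.append(row)
        outcome_col = sanitize_identifier(config.outcome.name)
        for pid in cohort.loc[cohort[outcome_col] == 1, "person_id"]:
            cond_rows.append((int(pid), config.outcome.concept_id, _random_date(rng)))
        conn.executemany(
            "INSERT INTO condition_occurrence VALUES (?, ?, ?, ?)",
            [(i + 1, *row) for i, row in enumerate(cond_rows)],
        )
        conn.executemany(
            "INSERT INTO observation VALUES (?, ?, ?, ?)",
            [(i + 1, *row) for i, row in enumerate(obs_rows)],
        )

        # --- measurements ------------------------------------------------
        meas_rows: list[tuple] = []
        if config.longitudinal is not None:
            lg = config.longitudinal
            grid = [
                f"{_GRID_START_YEAR + k}-01-15" for k in range(lg.n_time_points)
            ]
            for pid in cohort["person_id"]:
                for date in grid:
                    if rng.random() >= lg.missing_rate:
                        value = float(rng.normal(lg.mean, lg.sd))
                        meas_rows.append(
                            (int(pid), lg.concept_id, date, round(value, 2), None)
                        )
        # qualitative antigen test on ~half the cohort
        for pid in cohort["person_id"]:
            if rng.random() < 0.5:
                result = POSITIVE_CONCEPT_ID if rng.random() < 0.3 else _LOCAL_BASE + 6
                meas_rows.append(
                    (int(pid), _LOCAL_BASE + 7, _random_date(rng), None, int(result))
                )
        conn.executemany(
            "INSERT INTO measurement VALUES (?, ?, ?, ?, ?, ?)",
            [(i + 1, *row) for i, row in enumerate(meas_rows)],
        )
        conn.commit()
    finally:
        conn.close()
    return destination


def partition_sites(
    db_path: str,
    n_sites: int,
    seed: int,
    destinations: Optional[Sequence[str]] = None,
) -> list[str]:
    """Split one CDM database into per-site databases.

    Persons are shuffled (by ``seed``) and dealt round-robin, so site sizes
    differ by at most one; every event row lands with its person; the
    concept vocabulary is replicated to every site.  Returns the site
    database paths.
    """
    conn = sqlite3.connect(f"file:{db_path}?mode=ro", uri=True)
    try:
        persons = [r[0] for r in conn.execute("SELECT person_id FROM person ORDER BY person_id")]
        if n_sites > len(persons):
            raise ConfigurationError(
                f"cannot split {len(persons)} persons over {n_sites} sites"
            )
        rng = np.random.default_rng(seed)
        shuffled = list(persons)
        rng.shuffle(shuffled)
        site_sets = [set(shuffled[i::n_sites]) for i in range(n_sites)]

        if destinations is None:
            stem, ext = os.path.splitext(db_path)
            destinations = [f"{stem}_site{i + 1}{ext or '.db'}" for i in range(n_sites)]
        if len(destinations) != n_sites:
            raise ConfigurationError("need one destination path per site")

        tables = [
            r[0]
            for r in conn.execute(
                "SELECT name FROM sqlite_master WHERE type='table' "
                "AND name NOT LIKE 'sqlite_%' ORDER BY name"
            )
        ]
        ddl = {
            r[0]: r[1]
            for r in conn.execute(
                "SELECT name, sql FROM sqlite_master WHERE type='table'"
            )
        }
        out_paths: list[str] = []
        for dest, person_set in zip(destinations, site_sets):
            if os.path.exists(dest):
                os.remove(dest)
            out = sqlite3.connect(dest)
            try:
                for table in tables:
                    out.execute(ddl[table])
                    cols = [r[1] for r in conn.execute(f'PRAGMA table_info("{table}")')]
                    placeholders = ", ".join("?" for _ in cols)
                    if "person_id" in [c.lower() for c in cols]:
                        rows = [
                            tuple(r)
                            for r in conn.execute(f'SELECT * FROM "{table}"')
                            if r[[c.lower() for c in cols].index("person_id")] in person_set
                        ]
                    else:
                        rows = [tuple(r) for r in conn.execute(f'SELECT * FROM "{table}"')]
                    out.executemany(
                        f'INSERT INTO "{table}" VALUES ({placeholders})', rows
                    )
                out.commit()
            finally:
                out.close()
            out_paths.append(dest)
        return out_paths
    finally:
        conn.close()
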
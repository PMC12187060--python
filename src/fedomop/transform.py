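"""Long-to-wide reshaping and concept handling for extracted OMOP tables.

The raw extraction is long format — one row per clinical event.  Analyses in
the DataSHIELD tradition want one row per person.  This module supplies the
bridge:

* concept translation (integer ``concept_id`` → vocabulary name),
* identifier sanitization for generated column names,
* the wide pivot, with chronological occurrence indexing for repeated events,
* time-point completion for longitudinal series (every person padded out to
  the union of observed time points, missing entries as NA),
* person-keyed left merges, and
* cohort filters extracted from an existing table without ever exposing the
  person ids themselves.

NA is a single sentinel (:data:`pandas.NA`), distinct from ``""`` and ``0``,
serialized as an empty field in CSV.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .cdm_schema import SqlDialect, SQLITE_DIALECT
from .db_access import EventRecordSet, QueryFilter
from .errors import DataError, SchemaError, StructuralError

__all__ = [
    "NA",
    "Vocabulary",
    "LongitudinalOptions",
    "WideDataset",
    "translate_concepts",
    "sanitize_identifier",
    "pivot_events_wide",
    "complete_time_points",
    "merge_on_person",
    "build_cohort_filter",
    "presence_indicators",
    "unpivot",
]

#: Missing-value sentinel used in wide tables.
NA = pd.NA


class Vocabulary:
    """A site's concept vocabulary: ``concept_id`` → ``concept_name``.

    Always loaded from the database's own ``concept`` table, so translation
    follows whatever vocabulary version the site actually runs.  Ids missing
    from the vocabulary degrade to the placeholder name ``concept_<id>``.
    """

    def __init__(self, mapping: Mapping[int, str]):
        self._names = {int(k): str(v) for k, v in mapping.items()}

    @classmethod
    def from_connection(cls, connection, dialect: SqlDialect = SQLITE_DIALECT) -> "Vocabulary":
        cur = connection.execute(
            "SELECT {cid}, {cname} FROM {tbl}".format(
                cid=dialect.quote("concept_id"),
                cname=dialect.quote("concept_name"),
                tbl=dialect.quote("concept"),
            )
        )
        return cls(dict(cur.fetchall()))

    def __len__(self) -> int:
        return len(self._names)

    def __contains__(self, concept_id: int) -> bool:
        return int(concept_id) in self._names

    def name_of(self, concept_id) -> str:
        try:
            cid = int(concept_id)
        except (TypeError, ValueError):
            return f"concept_{concept_id}"
        return self._names.get(cid, f"concept_{cid}")


@dataclass(frozen=True)
class LongitudinalOptions:
    """How repeated events per person are handled.

    ``mode='long'`` keeps one row per event; ``mode='wide'`` produces
    time-indexed columns per person.  ``complete_time_points`` pads every
    person's series out to the union of time points observed across the whole
    dataset (NA where absent) before reshaping.  ``date_column`` names the
    chronological ordering column; when ``None`` the table's first
    ``*_start_date``, else ``*_date``, else ``*_datetime`` column is used.
    """

    mode: str = "wide"
    complete_time_points: bool = False
    date_column: Optional[str] = None

    def __post_init__(self) -> None:
        if self.mode not in ("long", "wide"):
            raise SchemaError(f"unknown longitudinal mode '{self.mode}'")


@dataclass
class WideDataset:
    """One row per person; concept × attribute (× occurrence) columns.

    ``data`` holds a ``person_id`` column plus value columns; ``provenance``
    maps each generated column back to ``(concept_id, source attribute,
    occurrence index)`` so every non-NA cell is traceable to exactly one
    source event row.
    """

    data: pd.DataFrame
    provenance: dict[str, tuple] = field(default_factory=dict)
    name: str = "dataset"
    person_column: str = "person_id"

    def __post_init__(self) -> None:
        if self.person_column not in self.data.columns:
            raise StructuralError(f"'{self.name}' lacks a '{self.person_column}' column")
        if self.data[self.person_column].duplicated().any():
            raise StructuralError(f"'{self.name}' has duplicate person rows")

    @property
    def person_ids(self) -> tuple[int, ...]:
        return tuple(int(p) for p in self.data[self.person_column])

    @property
    def columns(self) -> tuple[str, ...]:
        return tuple(c for c in self.data.columns if c != self.person_column)

    def __len__(self) -> int:
        return len(self.data)

    def to_csv(self, path) -> None:
        """RFC-4180 CSV with a header row; NA cells serialize as empty."""
        self.data.to_csv(path, index=False, na_rep="")

    @classmethod
    def from_csv(cls, path, name: str = "dataset") -> "WideDataset":
        df = pd.read_csv(path)
        return cls(data=df.convert_dtypes(), name=name)


def translate_concepts(records: EventRecordSet, vocabulary: Vocabulary) -> EventRecordSet:
    """Replace every ``*_concept_id`` value with its vocabulary name.

    A pure relabeling: row count, column set and non-concept columns are
    unchanged.  Missing names degrade to ``concept_<id>``; NULLs stay NULL.
    """
    concept_idx = [
        i for i, c in enumerate(records.columns) if c.lower().endswith("_concept_id")
    ]
    if not concept_idx:
        return EventRecordSet(
            records.table_name, records.columns, list(records.rows), records.person_column
        )
    new_rows = []
    for row in records.rows:
        row = list(row)
        for i in concept_idx:
            if row[i] is not None:
                row[i] = vocabulary.name_of(row[i])
        new_rows.append(tuple(row))
    return EventRecordSet(
        records.table_name, records.columns, new_rows, records.person_column
    )


def sanitize_identifier(concept_name: str) -> str:
    """Concept name → safe column identifier.

    Lowercase; every run of non-alphanumerics collapses to a single
    underscore; leading/trailing runs are stripped; a leading digit gets an
    underscore prefix.  Deterministic, so the same vocabulary always produces
    the same columns.
    """
    if not concept_name:
        raise DataError("cannot sanitize an empty name")
    s = re.sub(r"[^0-9a-z]+", "_", concept_name.lower()).strip("_")
    if not s:
        raise DataError(f"name {concept_name!r} contains no alphanumeric characters")
    if s[0].isdigit():
        s = "_" + s
    return s


def _default_date_column(columns: Sequence[str]) -> Optional[str]:
    for suffix in ("_start_date", "_date", "_datetime"):
        for c in columns:
            if c.lower().endswith(suffix):
                return c
    return None


def _parse_dates(series: pd.Series, table: str, column: str) -> pd.Series:
    try:
        return pd.to_datetime(series, errors="raise")
    except (ValueError, TypeError) as exc:
        raise DataError(
            f"unparseable date in table '{table}', column '{column}': {exc}"
        ) from exc


def pivot_events_wide(
    records: EventRecordSet,
    concept_column: str,
    attribute_columns: Sequence[str],
    options: LongitudinalOptions = LongitudinalOptions(),
    vocabulary: Optional[Vocabulary] = None,
) -> WideDataset:
    """Reshape an event table to one row per person.

    Each concept × attribute pair becomes a column named
    ``<sanitized concept>.<attribute>``; when a concept recurs for some
    person the occurrence index ``.<k>`` (1-based, chronological by the date
    column, ties broken by source primary key order) is appended.  Persons
    lacking a concept get NA.  Two distinct concept ids that sanitize to the
    same name are disambiguated by appending ``_<concept_id>``.
    """
    if records.person_column is None:
        raise StructuralError(f"'{records.table_name}' has no person column")
    for col in (concept_column, *attribute_columns):
        if col not in records.columns:
            raise SchemaError(f"'{records.table_name}' has no column '{col}'")

    df = records.to_frame()
    person_col = records.person_column
    persons = sorted(df[person_col].dropna().unique().tolist())

    date_col = options.date_column or _default_date_column(records.columns)
    order = pd.Series(range(len(df)), index=df.index)  # source (pk) order
    if date_col is not None and date_col in df.columns and len(df):
        dates = _parse_dates(df[date_col], records.table_name, date_col)
        df = df.assign(__date=dates, __order=order).sort_values(
            ["__date", "__order"], kind="stable"
        )
    else:
        df = df.assign(__order=order)

    df = df[df[concept_column].notna()]
    df = df.assign(__occ=df.groupby([person_col, concept_column]).cumcount() + 1)

    # concept id -> base column name, with collision disambiguation
    concept_ids = sorted(df[concept_column].unique().tolist())
    base_names: dict = {}
    for cid in concept_ids:
        label = vocabulary.name_of(cid) if vocabulary is not None else f"concept_{cid}"
        base_names[cid] = sanitize_identifier(label)
    by_name: dict[str, list] = {}
    for cid, nm in base_names.items():
        by_name.setdefault(nm, []).append(cid)
    for nm, cids in by_name.items():
        if len(cids) > 1:
            for cid in cids:
                base_names[cid] = f"{nm}_{int(cid)}"

    max_occ = df.groupby(concept_column)["__occ"].max().to_dict()

    cells: dict[str, dict] = {}
    provenance: dict[str, tuple] = {}
    attr_list = list(attribute_columns)
    row_iter = zip(
        df[person_col],
        df[concept_column],
        df["__occ"],
        df[attr_list].itertuples(index=False, name=None) if attr_list else iter(() for _ in range(len(df))),
    )
    for person, cid, occ, attr_values in row_iter:
        occ = int(occ)
        for attr, value in zip(attr_list, attr_values):
            col = f"{base_names[cid]}.{attr}"
            if max_occ[cid] > 1:
                col = f"{col}.{occ}"
            cells.setdefault(col, {})[person] = value
            provenance.setdefault(col, (cid, attr, occ if max_occ[cid] > 1 else 1))

    def order_key(col: str) -> tuple:
        cid, attr, occ = provenance[col]
        return (base_names[cid], list(attribute_columns).index(attr), occ)

    data = pd.DataFrame({person_col: persons})
    for col in sorted(cells, key=order_key):
        series = pd.Series([cells[col].get(p, NA) for p in persons], dtype="object")
        data[col] = series
    data = data.rename(columns={person_col: "person_id"})
    return WideDataset(
        data=data, provenance=provenance, name=records.table_name
    )


def unpivot(wide: WideDataset) -> pd.DataFrame:
    """Recover the deduplicated long table via provenance.

    Returns one row per non-NA cell: ``person_id, concept_id, attribute,
    occurrence, value``.  The round trip pivot→unpivot conserves events.
    """
    out = []
    for col in wide.columns:
        if col not in wide.provenance:
            continue
        cid, attr, occ = wide.provenance[col]
        for person, value in zip(wide.data["person_id"], wide.data[col]):
            if value is not NA and not pd.isna(value):
                out.append((person, cid, attr, occ, value))
    return pd.DataFrame(
        out, columns=["person_id", "concept_id", "attribute", "occurrence", "value"]
    )


def complete_time_points(records: EventRecordSet, date_column: str) -> EventRecordSet:
    """Pad every person's series out to the union of observed time points.

    Missing entries are inserted with the correct time index and NA in every
    other non-person column; original entries are untouched.  Idempotent:
    once all persons share all time points the input is returned unchanged
    (up to row order, which is person-then-date).
    """
    if records.person_column is None:
        raise StructuralError(f"'{records.table_name}' has no person column")
    if date_column not in records.columns:
        raise SchemaError(f"'{records.table_name}' has no column '{date_column}'")
    if not records.rows:
        return records

    df = records.to_frame()
    parsed = _parse_dates(df[date_column], records.table_name, date_column)
    person_col = records.person_column

    all_points = sorted(parsed.dropna().unique().tolist())
    persons = df[person_col].dropna().unique().tolist()
    have: dict = {
        p: set(parsed[df[person_col] == p].dropna().tolist()) for p in persons
    }

    new_rows = [tuple(r) for r in records.rows]
    date_idx = records.columns.index(date_column)
    person_idx = records.columns.index(person_col)
    # original string form of each time point, so inserted rows match the
    # source column's representation
    rendering = {}
    for raw, ts in zip(df[date_column], parsed):
        if ts not in rendering:
            rendering[ts] = raw
    for p in persons:
        for ts in all_points:
            if ts not in have[p]:
                row = [None] * len(records.columns)
                row[person_idx] = p
                row[date_idx] = rendering[ts]
                new_rows.append(tuple(row))

    new_rows.sort(key=lambda r: (str(r[person_idx]), str(r[date_idx])))
    return EventRecordSet(records.table_name, records.columns, new_rows, person_col)


def merge_on_person(left: WideDataset, right: WideDataset) -> WideDataset:
    """Left join on person id; the left table is the cohort anchor.

    Persons present only on the right are dropped; column collisions are
    suffixed ``_x``/``_y``.  Either side carrying duplicate person rows is a
    structural error (enforced at construction, re-checked here).
    """
    for side in (left, right):
        if side.data["person_id"].duplicated().any():
            raise StructuralError(f"'{side.name}' has duplicate person rows")
    merged = left.data.merge(
        right.data, on="person_id", how="left", suffixes=("_x", "_y")
    )
    provenance = {}
    collisions = (set(left.columns) & set(right.columns)) - {"person_id"}
    for src, suffix in ((left, "_x"), (right, "_y")):
        for col, prov in src.provenance.items():
            out_col = col + suffix if col in collisions else col
            provenance[out_col] = prov
    return WideDataset(data=merged, provenance=provenance, name=left.name)


def build_cohort_filter(existing_table: WideDataset) -> QueryFilter:
    """Cohort restriction: reuse an existing table's person set as a filter.

    The returned filter carries the ids internally (so pushdown works) but —
    like everything server-side — never serializes them in its repr; the
    client layer only ever triggers its use.  An empty table yields an
    empty-set filter, which legally matches zero rows downstream.
    """
    return QueryFilter(person_ids=frozenset(int(p) for p in existing_table.person_ids))


def presence_indicators(wide: WideDataset) -> WideDataset:
    """Collapse a pivoted table to one 0/1 column per concept.

    A person scores 1 on a concept iff any of that concept's columns is
    non-NA for them — i.e. at least one recorded event — else 0.  This is the
    standard recoding that turns extracted condition/observation tables into
    binary regression predictors.
    """
    concept_cols: dict = {}
    base_name: dict = {}
    for col in wide.columns:
        if col not in wide.provenance:
            continue
        cid = wide.provenance[col][0]
        concept_cols.setdefault(cid, []).append(col)
        base_name.setdefault(cid, col.split(".")[0])

    data = pd.DataFrame({"person_id": wide.data["person_id"]})
    provenance = {}
    for cid in sorted(concept_cols, key=lambda c: base_name[c]):
        cols = concept_cols[cid]
        present = wide.data[cols].notna().any(axis=1).astype(int)
        data[base_name[cid]] = present
        provenance[base_name[cid]] = (cid, "presence", 1)
    return WideDataset(data=data, provenance=provenance, name=wide.name)
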
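"""Read-only, parameterized SQL against an OMOP CDM source.

Person/concept/column filters are pushed down to the database so that only
the rows a request actually needs ever leave it.  Every literal is bound as a
query parameter — nothing user-supplied is interpolated into SQL text — and
every generated statement is a single SELECT.  Large ``IN`` lists are split
into batches of at most :data:`IN_BATCH_SIZE` placeholders and the results
concatenated; batching is invisible in the result, which is re-ordered by the
table's primary key.
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .cdm_schema import ColumnKind, SqlDialect, SQLITE_DIALECT, TableDescriptor
from .errors import RetrievalError, SchemaError, UsageError

__all__ = [
    "IN_BATCH_SIZE",
    "QueryFilter",
    "EventRecordSet",
    "build_select",
    "fetch_filtered",
    "concept_person_counts",
]

#: Maximum placeholders per IN list; 999 is the lowest common denominator
#: among embedded engines' default limits.
IN_BATCH_SIZE = 999


@dataclass(frozen=True)
class QueryFilter:
    """Person/concept/column selection pushed into the WHERE clause.

    An *absent* filter (``None``) means unrestricted; an *empty* set means
    "match nothing" and yields zero rows.  The repr never exposes the ids it
    carries — cohort filters are built server-side from tables the client is
    not allowed to see.
    """

    person_ids: Optional[frozenset[int]] = None
    concept_ids: Optional[frozenset[int]] = None
    columns: Optional[tuple[str, ...]] = None

    def __repr__(self) -> str:  # opaque by design
        def show(s):
            return "absent" if s is None else f"<{len(s)} ids>"

        cols = "absent" if self.columns is None else list(self.columns)
        return (
            f"QueryFilter(person_ids={show(self.person_ids)}, "
            f"concept_ids={show(self.concept_ids)}, columns={cols})"
        )


@dataclass
class EventRecordSet:
    """Long-format extraction result: one row per clinical event."""

    table_name: str
    columns: tuple[str, ...]
    rows: list[tuple]
    person_column: Optional[str]

    def __post_init__(self) -> None:
        for row in self.rows:
            if len(row) != len(self.columns):
                raise SchemaError(
                    f"row width {len(row)} != column count {len(self.columns)} "
                    f"in '{self.table_name}'"
                )

    def __len__(self) -> int:
        return len(self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=list(self.columns))

    def distinct_person_count(self) -> int:
        if self.person_column is None:
            raise UsageError(f"'{self.table_name}' has no person column")
        idx = self.columns.index(self.person_column)
        return len({row[idx] for row in self.rows if row[idx] is not None})


def _person_column(table: TableDescriptor) -> Optional[str]:
    return table.person_column


def build_select(
    table: TableDescriptor,
    query_filter: QueryFilter,
    concept_column: Optional[str] = None,
    dialect: SqlDialect = SQLITE_DIALECT,
) -> tuple[str, list]:
    """Render one parameterized SELECT for a filtered view of ``table``.

    Returns ``(sql, params)``.  Column order follows the request (or the
    table's schema order when no column subset is given).  Empty-set filters
    compile to a contradiction predicate so execution returns zero rows.
    """
    known = {c.lower(): c for c in table.column_names}
    if query_filter.columns is not None:
        for col in query_filter.columns:
            if col.lower() not in known:
                raise SchemaError(f"table '{table.name}' has no column '{col}'")
        select_cols = [known[c.lower()] for c in query_filter.columns]
    else:
        select_cols = list(table.column_names)

    if query_filter.concept_ids is not None and concept_column is None:
        raise UsageError("concept filter requires a concept_column")
    if concept_column is not None and concept_column.lower() not in known:
        raise SchemaError(f"table '{table.name}' has no column '{concept_column}'")

    predicates: list[str] = []
    params: list = []

    def add_in(column: str, values: frozenset[int]) -> None:
        if not values:
            predicates.append("1 = 0")
            return
        ordered = sorted(values)
        placeholders = ", ".join("?" for _ in ordered)
        predicates.append(f"{dialect.quote(column)} IN ({placeholders})")
        params.extend(ordered)

    if query_filter.person_ids is not None:
        person_col = _person_column(table)
        if person_col is None:
            raise SchemaError(f"table '{table.name}' has no person column")
        add_in(person_col, query_filter.person_ids)
    if query_filter.concept_ids is not None:
        add_in(concept_column, query_filter.concept_ids)

    sql = "SELECT {cols} FROM {table}".format(
        cols=", ".join(dialect.quote(c) for c in select_cols),
        table=dialect.quote(table.name),
    )
    if predicates:
        sql += " WHERE " + " AND ".join(predicates)
    return sql, params


def _chunks(values: Optional[frozenset[int]], size: int):
    if values is None:
        yield None
        return
    ordered = sorted(values)
    if not ordered:
        yield frozenset()
        return
    for i in range(0, len(ordered), size):
        yield frozenset(ordered[i : i + size])


def fetch_filtered(
    connection,
    table: TableDescriptor,
    query_filter: QueryFilter = QueryFilter(),
    dialect: SqlDialect = SQLITE_DIALECT,
    batch_size: int = IN_BATCH_SIZE,
) -> EventRecordSet:
    """Execute a pushed-down filtered fetch.

    Contract: the result equals fetching the whole table and filtering in
    memory (as a row multiset).  Id sets larger than ``batch_size`` are split
    into several queries whose results are concatenated and re-sorted by the
    table's primary key, so the batch size never shows in the output.
    """
    concept_col = table.concept_column
    if query_filter.concept_ids is not None and concept_col is None:
        raise UsageError(f"table '{table.name}' has no concept column to filter on")

    rows: list[tuple] = []
    columns: Optional[tuple[str, ...]] = None
    try:
        for person_chunk in _chunks(query_filter.person_ids, batch_size):
            for concept_chunk in _chunks(query_filter.concept_ids, batch_size):
                sub = QueryFilter(
                    person_ids=person_chunk,
                    concept_ids=concept_chunk,
                    columns=query_filter.columns,
                )
                sql, params = build_select(table, sub, concept_col, dialect)
                cur = connection.execute(sql, params)
                if columns is None:
                    columns = tuple(d[0] for d in cur.description)
                rows.extend(tuple(r) for r in cur.fetchall())
    except sqlite3.Error as exc:
        raise RetrievalError(f"query against table '{table.name}' failed: {exc}") from exc

    if columns is None:  # zero batches cannot happen, but keep the type tight
        columns = tuple(query_filter.columns or table.column_names)

    pk = table.primary_key
    if pk is not None and pk in columns:
        idx = columns.index(pk)
        rows.sort(key=lambda r: (r[idx] is None, r[idx]))

    person_col = _person_column(table)
    if person_col is not None and person_col not in columns:
        person_col = None
    return EventRecordSet(
        table_name=table.name, columns=columns, rows=rows, person_column=person_col
    )


def concept_person_counts(
    connection,
    table: TableDescriptor,
    dialect: SqlDialect = SQLITE_DIALECT,
) -> dict[int, int]:
    """Unique-person count per concept: the raw material of the data catalog.

    ``COUNT(DISTINCT person)`` grouped by the table's defining concept
    column; concepts absent from the table are absent from the mapping.
    """
    concept_col = table.concept_column
    person_col = _person_column(table)
    if concept_col is None or person_col is None:
        raise UsageError(
            f"'{table.name}' is not a domain table (needs person and concept columns)"
        )
    sql = (
        "SELECT {concept}, COUNT(DISTINCT {person}) FROM {table} "
        "WHERE {concept} IS NOT NULL GROUP BY {concept}"
    ).format(
        concept=dialect.quote(concept_col),
        person=dialect.quote(person_col),
        table=dialect.quote(table.name),
    )
    try:
        cur = connection.execute(sql)
    except sqlite3.Error as exc:
        raise RetrievalError(f"query against table '{table.name}' failed: {exc}") from exc
    return {int(cid): int(n) for cid, n in cur.fetchall()}
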
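"""Runtime OMOP CDM schema introspection.

The OMOP Common Data Model stores clinical events in domain tables
(condition_occurrence, measurement, observation, ...) that hang off a central
``person`` table and reference a ``concept`` vocabulary table.  Table layout
shifts between CDM versions, so nothing here hard-codes a version: the schema
is scanned at runtime and columns are classified purely by naming pattern —

* ``person_id``                 → link to the person anchor
* ``*_concept_id``              → link into the vocabulary
* ``*_id`` whose stem names a table → ordinary foreign key
* ``*_date`` / ``*_datetime``   → event date
* anything else                 → value column (or ``other`` for ``*_id``
                                  columns whose stem matches no table)

The classification drives a :class:`SchemaGraph` of foreign-key edges used to
resolve join paths between any two tables, however many intermediary hops the
CDM version puts between them.
"""

from __future__ import annotations

import sqlite3
from collections import deque
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .errors import DatabaseConnectionError, SchemaError, UnreachableTableError

__all__ = [
    "ColumnKind",
    "TableDescriptor",
    "SchemaGraph",
    "SqlDialect",
    "SQLITE_DIALECT",
    "register_dialect",
    "get_dialect",
    "classify_column",
    "introspect_schema",
    "resolve_join_path",
]


class ColumnKind(str, Enum):
    PERSON_LINK = "person_link"
    CONCEPT_LINK = "concept_link"
    FOREIGN_KEY = "foreign_key"
    DATE = "date"
    VALUE = "value"
    OTHER = "other"


def classify_column(column_name: str, known_tables: Iterable[str]) -> ColumnKind:
    """Classify a single column by naming pattern.

    Rules are applied in strict precedence order: person link, concept link,
    foreign key (``*_id`` whose stem, case-insensitively, names a known
    table), date, then value.  ``*_id`` columns whose stem matches no table
    classify as ``other`` and are preserved untouched downstream.
    """
    if not column_name:
        raise SchemaError("column name must be non-empty")
    name = column_name.lower()
    if name == "person_id":
        return ColumnKind.PERSON_LINK
    if name.endswith("_concept_id"):
        return ColumnKind.CONCEPT_LINK
    if name.endswith("_id"):
        stem = name[: -len("_id")]
        if stem in {t.lower() for t in known_tables}:
            return ColumnKind.FOREIGN_KEY
        return ColumnKind.OTHER
    if name.endswith("_date") or name.endswith("_datetime"):
        return ColumnKind.DATE
    return ColumnKind.VALUE


@dataclass(frozen=True)
class TableDescriptor:
    """One physical table: ordered columns with their classification."""

    name: str
    columns: tuple[tuple[str, ColumnKind], ...]
    row_count: int

    def __post_init__(self) -> None:
        lowered = [c.lower() for c, _ in self.columns]
        if len(set(lowered)) != len(lowered):
            raise SchemaError(f"duplicate column names in table '{self.name}'")
        if self.row_count < 0:
            raise SchemaError("row_count must be nonnegative")

    @property
    def column_names(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.columns)

    def kind_of(self, column: str) -> ColumnKind:
        for c, k in self.columns:
            if c.lower() == column.lower():
                return k
        raise SchemaError(f"table '{self.name}' has no column '{column}'")

    def columns_of_kind(self, kind: ColumnKind) -> tuple[str, ...]:
        return tuple(c for c, k in self.columns if k is kind)

    @property
    def person_column(self) -> str | None:
        cols = self.columns_of_kind(ColumnKind.PERSON_LINK)
        return cols[0] if cols else None

    @property
    def primary_key(self) -> str | None:
        """OMOP convention: table ``t`` keys its rows on column ``t_id``."""
        candidate = f"{self.name.lower()}_id"
        for c, _ in self.columns:
            if c.lower() == candidate:
                return c
        return None

    @property
    def concept_column(self) -> str | None:
        """The table's defining concept column: ``<table>_concept_id`` if
        present, else the first concept link in schema order."""
        cols = self.columns_of_kind(ColumnKind.CONCEPT_LINK)
        if not cols:
            return None
        preferred = f"{self.name.lower()}_concept_id"
        for c in cols:
            if c.lower() == preferred:
                return c
        return cols[0]

    @property
    def is_domain_table(self) -> bool:
        """Domain tables carry one row per clinical event: they link a person
        to a concept.  The person anchor table itself is not a domain table —
        its person link is its own primary key, not an event reference."""
        return (
            self.person_column is not None
            and self.concept_column is not None
            and self.person_column.lower() != f"{self.name.lower()}_id"
        )


@dataclass(frozen=True)
class SchemaGraph:
    """Tables plus the foreign-key edges discovered among them.

    Edges are stored as ``(from_table, fk_column, to_table)``; construction is
    deterministic for a fixed schema.
    """

    tables: Mapping[str, TableDescriptor]
    edges: frozenset[tuple[str, str, str]]

    def __post_init__(self) -> None:
        for from_t, col, to_t in self.edges:
            if from_t not in self.tables or to_t not in self.tables:
                raise SchemaError(f"edge ({from_t}, {col}, {to_t}) references unknown table")
            if col.lower() not in {c.lower() for c in self.tables[from_t].column_names}:
                raise SchemaError(f"edge column '{col}' missing from table '{from_t}'")

    def table(self, name: str) -> TableDescriptor:
        for t, desc in self.tables.items():
            if t.lower() == name.lower():
                return desc
        raise SchemaError(f"no such table: '{name}'")


# ---------------------------------------------------------------------------
# Dialect seam: the two schema-interaction queries (list tables, list columns)
# plus identifier quoting are the only DBMS-specific pieces; new dialects
# register here.
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SqlDialect:
    name: str
    list_tables_sql: str
    list_columns_sql: str  # templated with {table} via quote()

    def list_tables(self, connection) -> list[str]:
        cur = connection.execute(self.list_tables_sql)
        return [row[0] for row in cur.fetchall()]

    def list_columns(self, connection, table: str) -> list[str]:
        cur = connection.execute(self.list_columns_sql.format(table=self.quote(table)))
        return [row[1] for row in cur.fetchall()]

    @staticmethod
    def quote(identifier: str) -> str:
        return '"' + identifier.replace('"', '""') + '"'


SQLITE_DIALECT = SqlDialect(
    name="sqlite",
    list_tables_sql=(
        "SELECT name FROM sqlite_master "
        "WHERE type = 'table' AND name NOT LIKE 'sqlite_%' ORDER BY name"
    ),
    list_columns_sql="PRAGMA table_info({table})",
)

_DIALECTS: dict[str, SqlDialect] = {"sqlite": SQLITE_DIALECT}


def register_dialect(dialect: SqlDialect) -> None:
    _DIALECTS[dialect.name] = dialect


def get_dialect(name: str) -> SqlDialect:
    try:
        return _DIALECTS[name]
    except KeyError:
        raise SchemaError(f"no registered SQL dialect named '{name}'") from None


def introspect_schema(connection, dialect: SqlDialect = SQLITE_DIALECT) -> SchemaGraph:
    """Scan a live database into a :class:`SchemaGraph`.

    One :class:`TableDescriptor` per physical table; edges are derived solely
    from column classification: person links point at the ``person`` table,
    concept links at the ``concept`` table, and stem-matched ``*_id`` columns
    at their stem table.  A table's own primary key (``note_id`` inside
    ``note``) produces no edge.  Idempotent: two scans of the same database
    yield identical graphs.
    """
    try:
        names = dialect.list_tables(connection)
    except sqlite3.Error as exc:  # pragma: no cover - driver-specific
        raise DatabaseConnectionError(f"cannot list tables: {exc}") from exc
    if not names:
        raise SchemaError("database exposes no tables")

    known = set(names)
    lower_to_name = {n.lower(): n for n in names}
    tables: dict[str, TableDescriptor] = {}
    edges: set[tuple[str, str, str]] = set()

    for name in sorted(names):
        cols = dialect.list_columns(connection, name)
        classified = tuple((c, classify_column(c, known)) for c in cols)
        (count,) = connection.execute(
            f"SELECT COUNT(*) FROM {dialect.quote(name)}"
        ).fetchone()
        tables[name] = TableDescriptor(name=name, columns=classified, row_count=count)

    for name, desc in tables.items():
        for col, kind in desc.columns:
            target: str | None = None
            if kind is ColumnKind.PERSON_LINK:
                target = lower_to_name.get("person")
            elif kind is ColumnKind.CONCEPT_LINK:
                target = lower_to_name.get("concept")
            elif kind is ColumnKind.FOREIGN_KEY:
                target = lower_to_name.get(col.lower()[: -len("_id")])
            if target is not None and target.lower() != name.lower():
                edges.add((name, col, target))

    return SchemaGraph(tables=tables, edges=frozenset(edges))


def resolve_join_path(
    schema: SchemaGraph, from_table: str, to_table: str
) -> list[tuple[str, str, str]]:
    """Shortest chain of foreign-key edges linking two tables.

    Edges are traversed undirected (a fact row points at person; joining
    person out to its facts walks the same edge backwards).  Among equal-length
    paths the tie-break is lexicographic by intermediate table name, making
    the result deterministic.  Returns the stored edge tuples in path order;
    empty iff ``from_table == to_table``.
    """
    src = schema.table(from_table).name
    dst = schema.table(to_table).name
    if src == dst:
        return []

    # undirected adjacency, neighbours explored in sorted order
    adjacency: dict[str, list[tuple[str, tuple[str, str, str]]]] = {}
    for edge in schema.edges:
        a, _, b = edge
        adjacency.setdefault(a, []).append((b, edge))
        adjacency.setdefault(b, []).append((a, edge))
    for nbrs in adjacency.values():
        nbrs.sort(key=lambda item: (item[0], item[1][1]))

    parent: dict[str, tuple[str, tuple[str, str, str]]] = {}
    queue: deque[str] = deque([src])
    seen = {src}
    while queue:
        node = queue.popleft()
        if node == dst:
            break
        for nbr, edge in adjacency.get(node, []):
            if nbr not in seen:
                seen.add(nbr)
                parent[nbr] = (node, edge)
                queue.append(nbr)
    if dst not in seen:
        raise UnreachableTableError(
            f"no join path from '{from_table}' to '{to_table}'"
        )

    path: list[tuple[str, str, str]] = []
    node = dst
    while node != src:
        node, edge = parent[node]
        path.append(edge)
    path.reverse()
    return path
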
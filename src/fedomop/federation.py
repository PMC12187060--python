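"""In-process simulation of the client / multi-server topology.

Each :class:`SiteServer` owns a read-only connection to its OMOP database,
its own disclosure settings, and a private symbol table of server-held
datasets.  The client layer may only (a) trigger assignments — receiving an
acknowledgement that carries column names but never rows — and (b) request
fixed-shape model aggregates.  Every outward message passes disclosure
validation, and the per-site transcript records exactly what the client was
shown, so opacity is testable.

The real deployment stack this stands in for (Opal resources, SSL/TLS,
OAuth) is transport, not method; the payload contract is identical.
"""

from __future__ import annotations

import os
import sqlite3
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cdm_schema import SchemaGraph, introspect_schema
from .db_access import EventRecordSet, QueryFilter, concept_person_counts, fetch_filtered
from .disclosure import DisclosureSettings, filter_concept_catalog, validate_output_table
from .errors import DatabaseConnectionError, DisclosureError, SchemaError, UsageError
from .fedglm import GLMSpec, irls_local_contribution
from .transform import (
    LongitudinalOptions,
    Vocabulary,
    WideDataset,
    complete_time_points,
    merge_on_person,
    pivot_events_wide,
    presence_indicators,
    translate_concepts,
)

__all__ = [
    "ExtractionSpec",
    "AssignmentAck",
    "ModelRequest",
    "AggregatePayload",
    "SiteServer",
    "create_site",
    "site_assign_dataset",
    "site_merge_symbols",
    "site_aggregate",
    "assign_indicator_analysis",
]


@dataclass(frozen=True)
class ExtractionSpec:
    """What a site should extract and how it should be shaped."""

    table: str
    filter: QueryFilter = QueryFilter()
    options: LongitudinalOptions = LongitudinalOptions()
    wide: bool = True
    indicators: bool = False
    attribute_columns: Optional[tuple[str, ...]] = None


@dataclass(frozen=True)
class AssignmentAck:
    """All the client learns from an assignment: success plus the surviving
    column names."""

    site_id: str
    symbol: str
    columns: tuple[str, ...]

    def __str__(self) -> str:
        return (
            f"[{self.site_id}] assigned '{self.symbol}' "
            f"({len(self.columns)} columns: {', '.join(self.columns)})"
        )


@dataclass(frozen=True)
class ModelRequest:
    """One IRLS iteration request broadcast by the client."""

    symbol: str
    spec: GLMSpec
    beta: np.ndarray


@dataclass(frozen=True)
class AggregatePayload:
    """The only thing a site may return from an aggregate call.

    Cross-product matrices, counts and deviance; shapes fixed by the model
    spec; no per-row data."""

    site_id: str
    n_obs: int
    info_matrix: np.ndarray
    score_vector: np.ndarray
    deviance: float

    def __str__(self) -> str:
        return (
            f"[{self.site_id}] aggregate payload: n_obs={self.n_obs}, "
            f"info {self.info_matrix.shape}, deviance={self.deviance:.6g}"
        )


class SiteServer:
    """One data-holding site: database, settings, and session symbols.

    Symbols live only inside the instance; nothing here serializes them
    outward.  ``transcript`` collects every client-visible message.
    """

    def __init__(self, site_id: str, connection, settings: DisclosureSettings):
        self.site_id = site_id
        self.settings = settings
        self._connection = connection
        self._symbols: dict[str, WideDataset] = {}
        self._schema: Optional[SchemaGraph] = None
        self._vocabulary: Optional[Vocabulary] = None
        self.transcript: list[str] = []

    # schema and vocabulary are introspected lazily, once
    @property
    def schema(self) -> SchemaGraph:
        if self._schema is None:
            self._schema = introspect_schema(self._connection)
        return self._schema

    @property
    def vocabulary(self) -> Vocabulary:
        if self._vocabulary is None:
            try:
                self.schema.table("concept")
                self._vocabulary = Vocabulary.from_connection(self._connection)
            except SchemaError:
                self._vocabulary = Vocabulary({})
        return self._vocabulary

    @property
    def connection(self):
        return self._connection

    def symbol_names(self) -> tuple[str, ...]:
        return tuple(sorted(self._symbols))

    def _bind(self, symbol: str, table: WideDataset) -> None:
        self._symbols[symbol] = table

    def _lookup(self, symbol: str) -> WideDataset:
        try:
            return self._symbols[symbol]
        except KeyError:
            raise UsageError(f"site '{self.site_id}' holds no symbol '{symbol}'") from None


def create_site(
    database_path: str,
    settings: DisclosureSettings = DisclosureSettings(),
    site_id: Optional[str] = None,
) -> SiteServer:
    """Connect a site to its database (read-only) with an empty symbol table."""
    if database_path != ":memory:" and not os.path.exists(database_path):
        raise DatabaseConnectionError(f"database not found: {database_path}")
    try:
        if database_path == ":memory:":
            connection = sqlite3.connect(":memory:")
        else:
            connection = sqlite3.connect(
                f"file:{database_path}?mode=ro", uri=True
            )
            connection.execute("SELECT 1")
    except sqlite3.Error as exc:
        raise DatabaseConnectionError(f"cannot open {database_path}: {exc}") from exc
    if site_id is None:
        site_id = os.path.splitext(os.path.basename(database_path))[0] or "site"
    return SiteServer(site_id=site_id, connection=connection, settings=settings)


def _default_attributes(descriptor) -> tuple[str, ...]:
    """Default pivot attributes: the table's date and value columns."""
    from .cdm_schema import ColumnKind

    attrs = [
        c
        for c, k in descriptor.columns
        if k in (ColumnKind.DATE, ColumnKind.VALUE)
    ]
    return tuple(attrs)


def site_assign_dataset(site: SiteServer, symbol: str, spec: ExtractionSpec) -> AssignmentAck:
    """Fetch, disclosure-filter, reshape, and bind a table server-side.

    Concepts represented by fewer unique persons than the site's threshold
    are removed before reshaping (their rows never reach the symbol), and
    the finished table must itself pass the unique-person check before the
    acknowledgement — which carries column names only — is returned.
    Re-assigning an existing symbol replaces it.
    """
    descriptor = site.schema.table(spec.table)
    records = fetch_filtered(site.connection, descriptor, spec.filter)

    # table-level gate first: an extracted subset representing too few
    # individuals is disclosive as a whole, before any reshaping
    if records.person_column is not None:
        validate_output_table(records, site.settings)
    if descriptor.is_domain_table:
        records = _drop_subthreshold_concepts(site, records, descriptor)

    if spec.options.complete_time_points:
        date_col = spec.options.date_column
        if date_col is None:
            from .transform import _default_date_column

            date_col = _default_date_column(records.columns)
        if date_col is None:
            raise UsageError(f"'{spec.table}' has no date column to complete against")
        records = complete_time_points(records, date_col)

    if spec.wide and descriptor.is_domain_table:
        attrs = spec.attribute_columns or _default_attributes(descriptor)
        wide = pivot_events_wide(
            records,
            concept_column=descriptor.concept_column,
            attribute_columns=attrs,
            options=spec.options,
            vocabulary=site.vocabulary,
        )
        if spec.indicators:
            wide = presence_indicators(wide)
    elif descriptor.person_column is not None and not descriptor.is_domain_table:
        # person-anchored registry table: already one row per person
        df = records.to_frame().rename(columns={records.person_column: "person_id"})
        wide = WideDataset(data=df, name=spec.table)
    else:
        # long representation: translated events stored as-is, person-keyed
        if records.person_column is None:
            raise SchemaError(f"'{spec.table}' has no person column to key on")
        translated = translate_concepts(records, site.vocabulary)
        df = translated.to_frame().rename(columns={translated.person_column: "person_id"})
        wide = _LongSymbol(df, name=spec.table)

    wide.name = symbol
    validate_output_table(wide, site.settings)
    site._bind(symbol, wide)
    ack = AssignmentAck(site_id=site.site_id, symbol=symbol, columns=tuple(wide.columns))
    site.transcript.append(str(ack))
    return ack


class _LongSymbol:
    """Server-held long-format table (many rows per person)."""

    def __init__(self, data: pd.DataFrame, name: str):
        self.data = data
        self.name = name

    @property
    def person_ids(self) -> tuple[int, ...]:
        return tuple(int(p) for p in self.data["person_id"].dropna().unique())

    @property
    def columns(self) -> tuple[str, ...]:
        return tuple(c for c in self.data.columns if c != "person_id")


def _drop_subthreshold_concepts(
    site: SiteServer, records: EventRecordSet, descriptor
) -> EventRecordSet:
    """Remove events of concepts carried by 1..threshold-1 unique persons in
    the fetched subset."""
    concept_col = descriptor.concept_column
    if concept_col not in records.columns or not records.rows:
        return records
    df = records.to_frame()
    counts = (
        df.dropna(subset=[concept_col])
        .groupby(concept_col)[records.person_column]
        .nunique()
        .to_dict()
    )
    allowed = set(
        filter_concept_catalog({int(c): int(n) for c, n in counts.items()}, site.settings)
    )
    keep = [
        tuple(r)
        for r in records.rows
        if r[records.columns.index(concept_col)] is None
        or int(r[records.columns.index(concept_col)]) in allowed
    ]
    return EventRecordSet(records.table_name, records.columns, keep, records.person_column)


def site_merge_symbols(
    site: SiteServer, symbol: str, left_symbol: str, right_symbol: str
) -> AssignmentAck:
    """Server-side person-keyed left merge of two held symbols."""
    merged = merge_on_person(site._lookup(left_symbol), site._lookup(right_symbol))
    merged.name = symbol
    validate_output_table(merged, site.settings)
    site._bind(symbol, merged)
    ack = AssignmentAck(site_id=site.site_id, symbol=symbol, columns=tuple(merged.columns))
    site.transcript.append(str(ack))
    return ack


def site_aggregate(site: SiteServer, request: ModelRequest) -> AggregatePayload:
    """Compute one IRLS contribution against a held symbol.

    Complete-case: rows with NA in any model variable are dropped
    site-locally.  Refused (opaquely) when the surviving row count is below
    the subset threshold or the parameters/observations ratio exceeds the
    site's GLM ratio limit.
    """
    table = site._lookup(request.symbol)
    spec = request.spec
    needed = [spec.outcome, *spec.predictors]
    for col in needed:
        if col not in table.data.columns:
            raise UsageError(
                f"symbol '{request.symbol}' at site '{site.site_id}' lacks column '{col}'"
            )
    frame = table.data[needed].dropna()
    n = len(frame)
    p = len(spec.term_names)
    if n < site.settings.subset_threshold:
        raise DisclosureError(
            f"site '{site.site_id}' refused aggregation on '{request.symbol}'"
        )
    if p / n > site.settings.glm_ratio_limit:
        raise DisclosureError(
            f"site '{site.site_id}' refused aggregation on '{request.symbol}'"
        )
    X = np.column_stack(
        [np.ones(n)] + [frame[c].to_numpy(dtype=float) for c in spec.predictors]
    )
    y = frame[spec.outcome].to_numpy(dtype=float)
    info, score, deviance, n_obs = irls_local_contribution(X, y, request.beta, spec.family)
    payload = AggregatePayload(
        site_id=site.site_id,
        n_obs=n_obs,
        info_matrix=info,
        score_vector=score,
        deviance=deviance,
    )
    site.transcript.append(str(payload))
    return payload


def assign_indicator_analysis(site: SiteServer, symbol: str = "analysis") -> AssignmentAck:
    """Build the standard person-level analysis table at a site.

    Anchors on the person table, then for every domain table pivots the
    disclosure-surviving concepts to presence indicators (1 = at least one
    recorded event) and left-merges them onto the anchor; persons without a
    merged table's events score 0 on its indicators.  This is the recoding a
    binary-predictor GLM needs.
    """
    person_desc = site.schema.table("person")
    person_records = fetch_filtered(site.connection, person_desc)
    df = person_records.to_frame().rename(
        columns={person_records.person_column: "person_id"}
    )
    anchor = WideDataset(data=df[["person_id"]], name="person")

    domain_tables = sorted(
        name
        for name, desc in site.schema.tables.items()
        if desc.is_domain_table and name.lower() != "person"
    )
    for name in domain_tables:
        descriptor = site.schema.table(name)
        records = fetch_filtered(site.connection, descriptor)
        records = _drop_subthreshold_concepts(site, records, descriptor)
        if not records.rows:
            continue
        wide = pivot_events_wide(
            records,
            concept_column=descriptor.concept_column,
            attribute_columns=_default_attributes(descriptor),
            vocabulary=site.vocabulary,
        )
        indicators = presence_indicators(wide)
        anchor = merge_on_person(anchor, indicators)
        indicator_cols = list(indicators.columns)
        anchor.data[indicator_cols] = (
            anchor.data[indicator_cols].fillna(0).astype(int)
        )

    anchor.name = symbol
    validate_output_table(anchor, site.settings)
    site._bind(symbol, anchor)
    ack = AssignmentAck(site_id=site.site_id, symbol=symbol, columns=tuple(anchor.columns))
    site.transcript.append(str(ack))
    return ack
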
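"""Client-facing exploration of a site's database.

Mirrors the exploration surface of the client package: list the tables the
schema scan found (flagging which are domain tables, i.e. person-linked
event tables with a concept column) and list the concepts a domain table
holds.  The concept inventory is disclosure-filtered *before* it reaches the
client — a concept carried by fewer unique persons than the site's subset
threshold never appears, so the catalog shows exactly the concepts that are
also retrievable.
"""

from __future__ import annotations

from dataclasses import dataclass

from .db_access import concept_person_counts
from .disclosure import filter_concept_catalog
from .errors import UsageError
from .federation import SiteServer

__all__ = ["TableInfo", "CatalogEntry", "list_tables", "list_concepts"]


@dataclass(frozen=True)
class TableInfo:
    name: str
    is_domain: bool
    row_count: int


@dataclass(frozen=True)
class CatalogEntry:
    table: str
    concept_id: int
    concept_name: str
    unique_person_count: int  # only counts >= threshold are ever populated


def list_tables(site: SiteServer) -> list[TableInfo]:
    """All tables at the site, with their classified role.

    Deterministic (sorted by name); stable across calls for an unchanged
    database.
    """
    return [
        TableInfo(name=name, is_domain=desc.is_domain_table, row_count=desc.row_count)
        for name, desc in sorted(site.schema.tables.items())
    ]


def list_concepts(site: SiteServer, table: str) -> list[CatalogEntry]:
    """Disclosure-filtered, translated concept inventory of a domain table.

    Counts are unique persons per concept; sub-threshold concepts are
    excluded entirely.  Sorted by concept name, ties broken by id.
    """
    descriptor = site.schema.table(table)
    if not descriptor.is_domain_table:
        raise UsageError(f"'{table}' is not a domain table")
    counts = concept_person_counts(site.connection, descriptor)
    surviving = filter_concept_catalog(counts, site.settings)
    entries = [
        CatalogEntry(
            table=descriptor.name,
            concept_id=cid,
            concept_name=site.vocabulary.name_of(cid),
            unique_person_count=count,
        )
        for cid, count in surviving.items()
    ]
    entries.sort(key=lambda e: (e.concept_name, e.concept_id))
    return entries
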
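"""Subset-size disclosure control over relational, multi-record data.

DataSHIELD's subset threshold (``nfilter.subset``) demands that any exposed
subset represent at least a minimum non-zero number of individuals.  OMOP
data is relational — many rows per person, spread over domain tables — so the
check is applied to the number of *unique persons* behind every exposed
object: catalog entries, extracted tables, and model aggregates alike.

A count of zero means absence, not disclosure, and passes; counts strictly
between zero and the threshold are blocked.  Refusal messages name the object
only, never the offending count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Union

from .db_access import EventRecordSet
from .errors import ConfigurationError, DisclosureError

__all__ = [
    "DisclosureSettings",
    "passes_subset_threshold",
    "filter_concept_catalog",
    "validate_output_table",
]


@dataclass(frozen=True)
class DisclosureSettings:
    """Per-site disclosure knobs.

    ``subset_threshold`` is the minimum non-zero unique-person count any
    exposed object may represent (default 5 — a deliberately conservative
    value; deployments set their own).  ``glm_ratio_limit`` caps the
    parameters-to-observations ratio a site will accept in a model-fitting
    request.
    """

    subset_threshold: int = 5
    glm_ratio_limit: float = 0.33

    def __post_init__(self) -> None:
        if self.subset_threshold < 1:
            raise ConfigurationError("subset_threshold must be >= 1")
        if not (0 < self.glm_ratio_limit <= 1):
            raise ConfigurationError("glm_ratio_limit must be in (0, 1]")


def passes_subset_threshold(unique_person_count: int, settings: DisclosureSettings) -> bool:
    """True iff the count is zero (absence) or at least the threshold."""
    if unique_person_count < 0:
        raise ConfigurationError("unique_person_count must be nonnegative")
    return unique_person_count == 0 or unique_person_count >= settings.subset_threshold


def filter_concept_catalog(
    counts: Mapping[int, int], settings: DisclosureSettings
) -> dict[int, int]:
    """Drop catalog entries representing 1..threshold-1 unique persons.

    Surviving entries are untouched; zero-count entries are dropped too (a
    concept nobody carries has nothing to catalog).
    """
    return {
        cid: n
        for cid, n in counts.items()
        if n > 0 and passes_subset_threshold(n, settings)
    }


def validate_output_table(records, settings: DisclosureSettings) -> None:
    """Gate any table before it crosses to the client layer.

    Accepts a long :class:`EventRecordSet` (distinct persons counted over its
    person column) or any person-keyed wide object exposing ``person_ids``
    (one row per person).  Raises :class:`DisclosureError` — naming the table
    only — when the distinct-person count is non-zero but below threshold.
    """
    if isinstance(records, EventRecordSet):
        name = records.table_name
        count = records.distinct_person_count()
    elif hasattr(records, "person_ids"):
        name = getattr(records, "name", "dataset")
        count = len(set(records.person_ids))
    else:
        raise ConfigurationError(
            "records must be an EventRecordSet or a person-keyed wide dataset"
        )
    if not passes_subset_threshold(count, settings):
        raise DisclosureError(
            f"table '{name}' withheld: it represents too few distinct individuals"
        )
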
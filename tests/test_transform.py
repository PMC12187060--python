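"""Reshaping: translation, sanitization, wide pivot, time completion, merge."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fedomop import (
    DataError,
    EventRecordSet,
    LongitudinalOptions,
    StructuralError,
    Vocabulary,
    WideDataset,
    build_cohort_filter,
    complete_time_points,
    merge_on_person,
    pivot_events_wide,
    presence_indicators,
    sanitize_identifier,
    translate_concepts,
    unpivot,
)

VOCAB = Vocabulary({9191: "Positive", 317009: "Asthma", 3024561: "Hemoglobin"})


# --- translation -----------------------------------------------------------


def _events(rows, columns=("measurement_id", "person_id", "value_as_concept_id")):
    return EventRecordSet("measurement", columns, rows, "person_id")


def test_translation_uses_site_vocabulary():
    records = _events([(1, 1, 9191)])
    out = translate_concepts(records, VOCAB)
    assert out.rows[0][2] == "Positive"


def test_translation_fallback_and_purity():
    records = _events([(1, 1, 424242), (2, 2, None)])
    out = translate_concepts(records, VOCAB)
    assert out.rows[0][2] == "concept_424242"
    assert out.rows[1][2] is None
    # pure relabeling: shape and non-concept columns unchanged
    assert len(out) == len(records)
    assert [r[:2] for r in out.rows] == [r[:2] for r in records.rows]


def test_translation_of_empty_set_is_empty():
    out = translate_concepts(_events([]), VOCAB)
    assert out.rows == []


# --- sanitization ----------------------------------------------------------


@pytest.mark.parametrize(
    "name,expected",
    [
        ("Vitamin D deficiency", "vitamin_d_deficiency"),
        ("SARS-COV2 (antigen)", "sars_cov2_antigen"),
        ("2,4-D exposure", "_2_4_d_exposure"),
        ("COPD", "copd"),
    ],
)
def test_sanitize(name, expected):
    assert sanitize_identifier(name) == expected


def test_sanitize_rejects_all_symbol_input():
    with pytest.raises(DataError):
        sanitize_identifier("***")


# --- wide pivot ------------------------------------------------------------

CONDITION_COLS = (
    "condition_occurrence_id",
    "person_id",
    "condition_concept_id",
    "condition_start_date",
)


def test_pivot_rows_per_person_and_na_for_absent_concept():
    records = EventRecordSet(
        "condition_occurrence",
        CONDITION_COLS,
        [(1, 1, 317009, "2020-01-01"), (2, 2, 9191, "2020-06-01")],
        "person_id",
    )
    wide = pivot_events_wide(
        records, "condition_concept_id", ("condition_start_date",), vocabulary=VOCAB
    )
    assert len(wide) == 2
    assert "asthma.condition_start_date" in wide.columns
    col = wide.data.set_index("person_id")["asthma.condition_start_date"]
    assert col[1] == "2020-01-01"
    assert pd.isna(col[2])


def test_pivot_orders_occurrences_chronologically():
    # later measurement inserted first: occurrence indices must follow dates
    records = EventRecordSet(
        "measurement",
        ("measurement_id", "person_id", "measurement_concept_id", "measurement_date", "value_as_number"),
        [
            (1, 1, 3024561, "2020-06-01", 12.8),
            (2, 1, 3024561, "2020-01-01", 13.5),
        ],
        "person_id",
    )
    wide = pivot_events_wide(
        records, "measurement_concept_id", ("value_as_number",), vocabulary=VOCAB
    )
    row = wide.data.iloc[0]
    assert row["hemoglobin.value_as_number.1"] == 13.5
    assert row["hemoglobin.value_as_number.2"] == 12.8


def test_pivot_disambiguates_name_collisions():
    vocab = Vocabulary({101: "Other", 202: "Other"})
    records = EventRecordSet(
        "condition_occurrence",
        CONDITION_COLS,
        [(1, 1, 101, "2019-01-01"), (2, 1, 202, "2019-02-01")],
        "person_id",
    )
    wide = pivot_events_wide(
        records, "condition_concept_id", ("condition_start_date",), vocabulary=vocab
    )
    assert "other_101.condition_start_date" in wide.columns
    assert "other_202.condition_start_date" in wide.columns


@st.composite
def event_tables(draw):
    n_persons = draw(st.integers(1, 6))
    concepts = draw(st.lists(st.sampled_from([317009, 9191, 3024561]), min_size=1, max_size=3, unique=True))
    rows = []
    pk = 1
    for person in range(1, n_persons + 1):
        for concept in concepts:
            k = draw(st.integers(0, 3))
            for i in range(k):
                rows.append((pk, person, concept, f"2019-0{(pk % 9) + 1}-01"))
                pk += 1
    return EventRecordSet("condition_occurrence", CONDITION_COLS, rows, "person_id")


@given(records=event_tables())
def test_pivot_conserves_events_and_round_trips(records):
    """No event silently duplicated or dropped; provenance recovers the long
    table."""
    wide = pivot_events_wide(
        records, "condition_concept_id", ("condition_start_date",), vocabulary=VOCAB
    )
    non_na_cells = int(wide.data[list(wide.columns)].notna().sum().sum())
    assert non_na_cells == len(records)

    recovered = unpivot(wide)
    got = sorted(
        zip(recovered["person_id"], recovered["concept_id"], recovered["value"])
    )
    expected = sorted((r[1], r[2], r[3]) for r in records.rows)
    assert got == expected


def test_pivot_requires_person_column():
    records = EventRecordSet("x", ("a", "b"), [(1, 2)], None)
    with pytest.raises(StructuralError):
        pivot_events_wide(records, "a", ("b",))


# --- time-point completion -------------------------------------------------

MEAS_COLS = ("measurement_id", "person_id", "measurement_date", "value_as_number")


def _series(rows):
    return EventRecordSet("measurement", MEAS_COLS, rows, "person_id")


def test_completion_pads_to_the_union_of_time_points():
    records = _series(
        [
            (1, 1, "2019-01-01", 10.0),
            (2, 1, "2019-02-01", 11.0),
            (3, 2, "2019-02-01", 12.0),
            (4, 2, "2019-03-01", 13.0),
        ]
    )
    out = complete_time_points(records, "measurement_date")
    df = out.to_frame()
    for person in (1, 2):
        dates = sorted(df[df["person_id"] == person]["measurement_date"])
        assert dates == ["2019-01-01", "2019-02-01", "2019-03-01"]
    # person 2 gets an NA entry at the time point it lacked
    inserted = df[(df["person_id"] == 2) & (df["measurement_date"] == "2019-01-01")]
    assert len(inserted) == 1 and inserted["value_as_number"].isna().all()
    # originals untouched
    assert (1, 1, "2019-01-01", 10.0) in [tuple(r) for r in out.rows]


def test_completion_is_idempotent_and_identity_when_complete():
    records = _series([(1, 1, "2019-01-01", 1.0), (2, 2, "2019-01-01", 2.0)])
    once = complete_time_points(records, "measurement_date")
    assert sorted(once.rows) == sorted(records.rows)
    twice = complete_time_points(once, "measurement_date")
    assert sorted(twice.rows) == sorted(once.rows)


def test_single_person_is_unchanged():
    records = _series([(1, 1, "2019-01-01", 1.0), (2, 1, "2019-05-01", 2.0)])
    out = complete_time_points(records, "measurement_date")
    assert sorted(out.rows) == sorted(records.rows)


def test_unparseable_date_names_table_and_column():
    records = _series([(1, 1, "not-a-date", 1.0)])
    with pytest.raises(DataError, match="measurement.*measurement_date"):
        complete_time_points(records, "measurement_date")


# --- merge -----------------------------------------------------------------


def _wide(persons, **cols):
    return WideDataset(data=pd.DataFrame({"person_id": persons, **cols}))


def test_left_merge_anchors_the_cohort():
    left = _wide([1, 2, 3], a=[10, 20, 30])
    right = _wide([2, 3, 4], b=[200, 300, 400])
    out = merge_on_person(left, right)
    assert list(out.data["person_id"]) == [1, 2, 3]
    assert pd.isna(out.data.loc[out.data["person_id"] == 1, "b"]).all()
    assert out.data.loc[out.data["person_id"] == 2, "b"].item() == 200


def test_merge_with_empty_right_is_identity_on_persons():
    left = _wide([1, 2], a=[1, 2])
    right = WideDataset(data=pd.DataFrame({"person_id": pd.Series([], dtype=int)}))
    out = merge_on_person(left, right)
    assert list(out.data["person_id"]) == [1, 2]
    assert set(out.columns) == {"a"}


def test_duplicate_person_rows_rejected():
    with pytest.raises(StructuralError):
        _wide([1, 1], a=[1, 2])


@given(
    left_persons=st.sets(st.integers(1, 12), min_size=1, max_size=8),
    right_persons=st.sets(st.integers(1, 12), min_size=0, max_size=8),
)
def test_merge_matches_nested_loop_oracle(left_persons, right_persons):
    left = _wide(sorted(left_persons), a=[p * 10 for p in sorted(left_persons)])
    right = _wide(sorted(right_persons), b=[p * 100 for p in sorted(right_persons)])
    out = merge_on_person(left, right)
    # brute-force nested-loop left join
    expected = {}
    for p in sorted(left_persons):
        match = [q for q in right_persons if q == p]
        expected[p] = (p * 100) if match else None
    got = {
        int(p): (None if pd.isna(b) else int(b))
        for p, b in zip(out.data["person_id"], out.data["b"])
    }
    assert got == expected


# --- cohort filter and indicators -----------------------------------------


def test_cohort_filter_carries_ids_but_never_shows_them():
    table = _wide([1, 5, 9], a=[0, 0, 0])
    qf = build_cohort_filter(table)
    assert qf.person_ids == frozenset({1, 5, 9})
    shown = repr(qf)
    for pid in (1, 5, 9):
        assert str(pid) not in shown.replace("3 ids", "")


def test_presence_indicators_binarize_by_concept():
    records = EventRecordSet(
        "condition_occurrence",
        CONDITION_COLS,
        [(1, 1, 317009, "2019-01-01"), (2, 1, 317009, "2019-02-01")],
        "person_id",
    )
    wide = pivot_events_wide(
        records, "condition_concept_id", ("condition_start_date",), vocabulary=VOCAB
    )
    ind = presence_indicators(wide)
    assert list(ind.columns) == ["asthma"]
    assert ind.data["asthma"].tolist() == [1]


# --- CSV round trip --------------------------------------------------------


def test_csv_round_trip_preserves_na(tmp_path):
    wide = _wide([1, 2], a=[1.5, None])
    path = tmp_path / "out.csv"
    wide.to_csv(path)
    text = path.read_text()
    assert text.splitlines()[2].endswith(",")  # NA serialized as empty field
    back = WideDataset.from_csv(path)
    assert back.data["a"].isna().tolist() == [False, True]
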
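"""Sequence construction, truncation, tie-breaks and cohort eligibility."""

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ehrseq.sequences import (
    SequenceError,
    TokenVocabulary,
    build_sequences,
    eligible_cohort,
    read_sequences,
    write_sequences,
)
from tests.conftest import make_records

INDEX = "2015-01-01"


def events_frame(rows):
    df = pd.DataFrame(rows, columns=["patient_id", "event_date", "medcode"])
    df["event_date"] = pd.to_datetime(df["event_date"])
    return df


def example_fixture():
    """One patient whose history reads, in date order: asthma, rheumatoid
    arthritis, depression, atrial fibrillation, depression."""
    code_map = pd.DataFrame({
        "medcode": ["m_asth", "m_ra", "m_depr1", "m_depr2", "m_af"],
        "disease": ["asthma", "rheumatoid arthritis", "depression",
                    "depression", "atrial fibrillation"],
    })
    events = events_frame([
        ("p1", "2001-03-01", "m_asth"),
        ("p1", "2004-07-15", "m_ra"),
        ("p1", "2008-01-02", "m_depr1"),
        ("p1", "2011-05-20", "m_af"),
        ("p1", "2013-02-10", "m_depr2"),
    ])
    records = make_records([
        {"patient_id": "p1", "birth_date": "1960-01-01",
         "registration_date": "1990-01-01"},
    ])
    return events, code_map, records


def test_disease_sequence_in_date_order():
    events, code_map, records = example_fixture()
    seqs = build_sequences(events, code_map, records, "diseases", INDEX)
    assert seqs["p1"].tokens == [
        "asthma", "rheumatoid arthritis", "depression",
        "atrial fibrillation", "depression"]
    assert seqs["p1"].visit_index == [1, 2, 3, 4, 5]
    assert seqs["p1"].age_years[0] == 41  # born 1960, event 2001
    assert seqs["p1"].calendar_year == [2001, 2004, 2008, 2011, 2013]


def test_medcode_vocabulary_keeps_fine_codes():
    events, code_map, records = example_fixture()
    seqs = build_sequences(events, code_map, records, "medcodes", INDEX)
    assert seqs["p1"].tokens == ["m_asth", "m_ra", "m_depr1", "m_af",
                                 "m_depr2"]


def test_truncation_keeps_most_recent_codes():
    code_map = pd.DataFrame({"medcode": ["m1"], "disease": ["d1"]})
    records = make_records([
        {"patient_id": "p1", "birth_date": "1950-01-01",
         "registration_date": "1990-01-01"}])
    dates = pd.date_range("2000-01-01", periods=130, freq="7D")
    events = events_frame([("p1", d, "m1") for d in dates])
    seqs = build_sequences(events, code_map, records, "diseases", INDEX,
                           max_len=128)
    s = seqs["p1"]
    assert len(s) == 128
    assert s.calendar_year[-1] == dates[-1].year
    # the two oldest events fall away
    assert s.visit_index[0] == 1 and s.visit_index == sorted(s.visit_index)


def test_single_event_patients_are_excluded():
    code_map = pd.DataFrame({"medcode": ["m1"], "disease": ["d1"]})
    records = make_records([
        {"patient_id": "p1", "birth_date": "1950-01-01",
         "registration_date": "1990-01-01"},
        {"patient_id": "p2", "birth_date": "1950-01-01",
         "registration_date": "1990-01-01"}])
    events = events_frame([("p1", "2010-01-01", "m1"),
                           ("p2", "2010-01-01", "m1"),
                           ("p2", "2011-01-01", "m1")])
    seqs = build_sequences(events, code_map, records, "diseases", INDEX)
    assert set(seqs) == {"p2"}


def test_same_day_ties_break_lexicographically_by_medcode():
    code_map = pd.DataFrame({"medcode": ["ma", "mb"],
                             "disease": ["da", "db"]})
    records = make_records([
        {"patient_id": "p1", "birth_date": "1950-01-01",
         "registration_date": "1990-01-01"}])
    events = events_frame([("p1", "2010-06-01", "mb"),
                           ("p1", "2010-06-01", "ma")])
    seqs = build_sequences(events, code_map, records, "medcodes", INDEX)
    assert seqs["p1"].tokens == ["ma", "mb"]
    assert seqs["p1"].visit_index == [1, 1]  # same date = same visit


def test_post_index_event_rejected():
    events, code_map, records = example_fixture()
    late = events.copy()
    late.loc[late.index[0], "event_date"] = pd.Timestamp("2015-06-01")
    with pytest.raises(SequenceError, match="index date"):
        build_sequences(late, code_map, records, "diseases", INDEX)


def test_unmapped_code_rejected():
    events, code_map, records = example_fixture()
    with pytest.raises(SequenceError, match="m_unknown"):
        build_sequences(
            pd.concat([events,
                       events_frame([("p1", "2010-01-01", "m_unknown")])]),
            code_map, records, "diseases", INDEX)


@settings(max_examples=25, deadline=None)
@given(st.lists(st.tuples(st.integers(0, 9), st.integers(0, 400)),
                min_size=2, max_size=200),
       st.integers(2, 60))
def test_truncation_commutes_with_category_mapping(events_spec, max_len):
    """Mapping codes to categories and truncating to the most recent
    max_len tokens give the same result in either order."""
    code_map = pd.DataFrame({"medcode": [f"m{i}" for i in range(10)],
                             "disease": [f"d{i % 3}" for i in range(10)]})
    records = make_records([
        {"patient_id": "p", "birth_date": "1950-01-01",
         "registration_date": "1990-01-01"}])
    base = pd.Timestamp("2000-01-01")
    events = events_frame([
        ("p", base + pd.Timedelta(days=off), f"m{c}")
        for c, off in events_spec])
    full_medcodes = build_sequences(events, code_map, records, "medcodes",
                                    INDEX, max_len=10 ** 6)
    truncated_diseases = build_sequences(events, code_map, records,
                                         "diseases", INDEX, max_len=max_len)
    mapping = dict(zip(code_map["medcode"], code_map["disease"]))
    mapped_then_truncated = [mapping[t]
                             for t in full_medcodes["p"].tokens][-max_len:]
    assert truncated_diseases["p"].tokens == mapped_then_truncated


def test_vocabulary_round_trip_and_specials(tmp_path):
    vocab = TokenVocabulary(["dz", "da", "db"])
    assert vocab.tokens[:5] == ["[PAD]", "[UNK]", "[CLS]", "[SEP]", "[MASK]"]
    assert vocab.n_codes == 3
    ids = vocab.encode(["da", "db", "dz", "nope"])
    assert vocab.decode(ids[:3]) == ["da", "db", "dz"]
    assert ids[3] == vocab.index["[UNK]"]
    vocab.to_tsv(tmp_path / "v.tsv")
    again = TokenVocabulary.from_tsv(tmp_path / "v.tsv")
    assert again.tokens == vocab.tokens


def test_sequence_jsonl_round_trip(tmp_path, small_sequences):
    path = tmp_path / "seqs.jsonl"
    write_sequences(small_sequences, path)
    again = read_sequences(path)
    assert set(again) == set(small_sequences)
    pid = next(iter(small_sequences))
    assert again[pid].tokens == small_sequences[pid].tokens
    assert again[pid].visit_index == small_sequences[pid].visit_index


def eligibility_fixture():
    """Ten patients, three violating cohort rules: late registration,
    pre-index death, deregistration before index."""
    ok = {"birth_date": "1960-01-01", "registration_date": "2000-01-01"}
    rows = [dict(patient_id=f"p{i}", **ok) for i in range(7)]
    rows.append({"patient_id": "p7", "birth_date": "1960-01-01",
                 "registration_date": "2014-07-01"})  # 6 months pre-index
    rows.append({"patient_id": "p8", "birth_date": "1960-01-01",
                 "registration_date": "2000-01-01",
                 "death_date": "2014-11-30"})  # died before index
    rows.append({"patient_id": "p9", "birth_date": "1960-01-01",
                 "registration_date": "2000-01-01",
                 "deregistration_date": "2014-06-01"})  # left before index
    return make_records(rows)


def test_eligible_cohort_applies_all_rules():
    records = eligibility_fixture()
    code_map = pd.DataFrame({"medcode": ["m1", "m2"],
                             "disease": ["d1", "d2"]})
    events = events_frame(
        [(f"p{i}", "2010-01-01", "m1") for i in range(10)]
        + [(f"p{i}", "2012-01-01", "m2") for i in range(10)])
    seqs = build_sequences(events, code_map, records, "diseases", INDEX)
    kept = eligible_cohort(records, seqs, INDEX)
    assert kept == {f"p{i}" for i in range(7)}


def test_eligibility_needs_two_distinct_diseases():
    records = eligibility_fixture()[:1]
    code_map = pd.DataFrame({"medcode": ["m1", "m2"],
                             "disease": ["d1", "d1"]})
    events = events_frame([("p0", "2010-01-01", "m1"),
                           ("p0", "2012-01-01", "m2")])
    seqs = build_sequences(events, code_map, records, "diseases", INDEX)
    assert eligible_cohort(records, seqs, INDEX) == set()
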
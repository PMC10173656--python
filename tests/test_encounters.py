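"""Data model: aggregation, filtering, feature assembly, labels, round-trip."""

import itertools

import numpy as np
import pandas as pd
import pytest

from labreduce.encounters import (AGE_COL, HGB_COL, HGB_IND_COL, HGBCHG_COL, IND_OFFSET,
                                  MAX_TIMESTEPS, SEX_COL, TDIFF_COL, DrawRecord,
                                  EncounterSequence, NoObservedHgbError, NormalRangeTable,
                                  Standardizer, UnknownAnalyteError, aggregate_hourly,
                                  apply_cohort_filters, build_sequence,
                                  encounters_to_tensors, load_cohort_csv, normality_label,
                                  split_cohort, stability_label, write_cohort_csv,
                                  ANALYTES)


# ----------------------------------------------------------------- labeling

@pytest.mark.parametrize("hgb,age,sex,expected", [
    (12.5, 40, "F", 1),   # adult woman above her 12.0 bound
    (11.0, 40, "F", 0),
    (12.0, 40, "F", 1),   # boundary counts as normal by default
    (10.5, 3, "M", 1),    # young-child band, bound 10.5
    (10.4, 3, "F", 0),
    (11.0, 9, "M", 1),    # school-age band, bound 11.0
    (10.9, 9, "F", 0),
    (14.0, 40, "M", 1),   # adult man, bound 14.0
    (13.9, 40, "M", 0),
    (12.0, 13, "F", 1),   # 13 falls in the adult rows
    (11.0, 12.5, "M", 1),  # 12.5 still in the 7-12y band
])
def test_normality_label_strata(hgb, age, sex, expected):
    assert normality_label(hgb, age, sex) == expected


def test_normality_boundary_switch():
    assert normality_label(12.0, 40, "F", boundary_normal=False) == 0


def test_normality_rejects_infants_and_nonpositive():
    with pytest.raises(ValueError):
        normality_label(12.0, 0.3, "F")
    with pytest.raises(ValueError):
        normality_label(0.0, 40, "F")


def test_stability_label_matches_bruteforce_rule():
    for prev, curr in itertools.product([0, 1, None], [0, 1]):
        expected = 0 if (prev == 1 and curr == 0) else 1
        assert stability_label(prev, curr) == expected


def test_normal_range_table_requires_ordered_bounds():
    from labreduce.encounters import NormalRangeRow
    with pytest.raises(ValueError):
        NormalRangeTable([NormalRangeRow(0.5, 7, "any", 14.0, 10.0)])


# -------------------------------------------------------------- aggregation

def test_aggregate_hourly_averages_duplicates():
    t0 = "2020-03-01T07:10:00"
    t1 = "2020-03-01T07:40:00"
    recs = aggregate_hourly(pd.DataFrame(
        [("e1", t0, "Hgb", 10.0), ("e1", t1, "Hgb", 11.0), ("e1", t0, "sbp", 110.0)],
        columns=["encounter_id", "timestamp", "variable", "value"]))
    (draw,) = recs["e1"]
    assert draw.values["Hgb"] == pytest.approx(10.5)
    assert draw.values["sbp"] == pytest.approx(110.0)


def test_aggregate_hourly_hour_indices_and_sparsity():
    rows = [("e1", "2020-01-01T02:30:00", "WBC", 9.0),
            ("e1", "2020-01-01T00:15:00", "Hgb", 10.0),
            ("e1", "2020-01-01T05:00:00", "Hgb", 9.0)]
    recs = aggregate_hourly(pd.DataFrame(rows, columns=["encounter_id", "timestamp",
                                                        "variable", "value"]))["e1"]
    assert [d.hour_index for d in recs] == [0, 2, 4]
    assert recs[1].observed("WBC") and not recs[1].observed("Hgb")


def test_aggregate_hourly_rejects_unknown_and_nonnumeric():
    with pytest.raises(UnknownAnalyteError):
        aggregate_hourly([("e", "2020-01-01", "Troponin", 1.0)])
    with pytest.raises(ValueError):
        aggregate_hourly([("e", "2020-01-01", "Hgb", "high")])


# ----------------------------------------------------------------- filters

def _enc(draws, enc_id="e", sex=0, age=40.0):
    return EncounterSequence(enc_id, sex, 0, age, draws)


def test_cohort_filters():
    single = _enc([DrawRecord(0, {"Hgb": 10.0}), DrawRecord(3, {"Na": 140.0})])
    hypo = _enc([DrawRecord(0, {"Hgb": 10.0, "sbp": 85.0}),
                 DrawRecord(2, {"Hgb": 9.5})])
    ok = _enc([DrawRecord(0, {"Hgb": 10.0, "sbp": 95.0}), DrawRecord(2, {"Hgb": 9.9}),
               DrawRecord(5, {"Hgb": 9.0})])
    kept = apply_cohort_filters([single, hypo, ok])
    assert kept == [ok]
    assert apply_cohort_filters([]) == []


# ----------------------------------------------------------- sequence build

def test_build_sequence_trims_caps_and_pads():
    draws = [DrawRecord(h, {"Hgb": 10.0}) for h in range(35)]
    enc, X, lab = build_sequence(draws, {"sex": "F", "age": 40})
    assert enc.length == MAX_TIMESTEPS
    assert X.shape == (30, 39)

    short, Xs, labs = build_sequence(draws[:4], {"sex": "F", "age": 40})
    assert np.all(Xs[4:] == 0.0)
    assert labs.o[:4].tolist() == [1, 1, 1, 1]


def test_build_sequence_change_and_time_columns():
    draws = [DrawRecord(0, {"Hgb": 9.0}), DrawRecord(6, {"Na": 140.0}),
             DrawRecord(9, {"Hgb": 9.7})]
    _, X, lab = build_sequence(draws, {"sex": "M", "age": 50})
    assert X[2, HGBCHG_COL] == pytest.approx(0.7)
    assert X[0, HGBCHG_COL] == 0.0          # first observation has no predecessor
    assert X[1, TDIFF_COL] == 6.0
    assert X[2, TDIFF_COL] == 3.0
    assert X[0, TDIFF_COL] == 0.0
    assert lab.v.tolist()[:3] == [9.0, 0.0, 9.7]


def test_build_sequence_window_bounded_by_hgb():
    draws = [DrawRecord(0, {"Na": 140.0}), DrawRecord(1, {"Hgb": 10.0}),
             DrawRecord(2, {"WBC": 5.0}), DrawRecord(3, {"Hgb": 11.0}),
             DrawRecord(4, {"K": 4.0})]
    enc, X, lab = build_sequence(draws, {"sex": "F", "age": 30})
    assert enc.length == 3
    assert lab.o[0] == 1 and lab.o[enc.length - 1] == 1
    with pytest.raises(NoObservedHgbError):
        build_sequence([DrawRecord(0, {"Na": 140.0})], {"sex": "F", "age": 30})


def test_indicator_iff_observed_on_synthetic(small_tensors):
    X, o = small_tensors.X, small_tensors.o
    # Hgb indicator column must mirror the observation flags exactly
    assert np.array_equal(X[:, :, HGB_IND_COL], o)
    # every analyte: value nonzero implies indicator set
    for k in range(17):
        observed = X[:, :, IND_OFFSET + k] > 0
        assert np.all(X[:, :, k][~observed] == 0.0)


def test_first_and_last_rows_have_hgb(small_tensors):
    o, L = small_tensors.o, small_tensors.seq_len
    assert np.all(o[:, 0] == 1)
    assert np.all(o[np.arange(len(L)), L - 1] == 1)


# -------------------------------------------------------------------- split

def test_split_cohort_deterministic_and_disjoint():
    encs = [f"e{i}" for i in range(100)]
    a1, b1 = split_cohort(encs, 0.8, seed=5)
    a2, b2 = split_cohort(encs, 0.8, seed=5)
    assert (a1, b1) == (a2, b2)
    assert len(a1) == 80 and len(b1) == 20
    assert set(a1).isdisjoint(b1)
    with pytest.raises(ValueError):
        split_cohort(encs, 1.0, seed=0)
    with pytest.raises(ValueError):
        split_cohort(encs[:1], 0.8, seed=0)


# ---------------------------------------------------------------- round-trip

def test_csv_roundtrip_preserves_tensors(small_cohort, tmp_path):
    subset = apply_cohort_filters(small_cohort)[:25]
    write_cohort_csv(subset, tmp_path / "events.csv", tmp_path / "demo.csv")
    back = load_cohort_csv(tmp_path / "events.csv", tmp_path / "demo.csv")
    t1 = encounters_to_tensors(subset)
    t2 = encounters_to_tensors(sorted(back, key=lambda e: t1.ids.index(e.encounter_id)))
    np.testing.assert_allclose(t1.X, t2.X)
    np.testing.assert_allclose(t1.y, t2.y)
    np.testing.assert_allclose(t1.z, t2.z)
    np.testing.assert_allclose(t1.v, t2.v)
    np.testing.assert_allclose(t1.o, t2.o)


# ------------------------------------------------------------ standardizer

def test_standardizer_preserves_padding_and_missing(small_tensors):
    std = Standardizer().fit(small_tensors)
    Xs = std.transform(small_tensors)
    T = np.arange(Xs.shape[1])
    padded = T[None, :] >= small_tensors.seq_len[:, None]
    assert np.all(Xs[padded] == 0.0)
    missing = small_tensors.X[:, :, IND_OFFSET + HGB_COL] == 0
    assert np.all(Xs[:, :, HGB_COL][missing] == 0.0)
    obs = (small_tensors.X[:, :, IND_OFFSET] > 0)  # Na observed entries
    assert abs(Xs[:, :, 0][obs].mean()) < 1e-8
    assert Xs[:, :, 0][obs].std() == pytest.approx(1.0, abs=1e-6)
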
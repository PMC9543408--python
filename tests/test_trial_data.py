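"""Data model, CSV round-trip, pattern classification, summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import estimandtools as et
from estimandtools.trial_data import PatternLabel, trailing_missing_run


# ---------------------------------------------------------------------------
# classify_pattern
# ---------------------------------------------------------------------------


def literal_pattern_rules(mask):
    """Brute-force transcription of the three dropout-pattern rules.

    Completers/quasicompleters: last visit observed (earlier visits may be
    intermittently missing) or only the last visit missing.  Late dropout:
    exactly the last two visits form the monotone missing tail.  Early
    dropout: the monotone missing tail starts at visit 2 .. V-2.
    """
    mask = list(mask)
    V = len(mask)
    if not any(mask):
        return PatternLabel.UNCLASSIFIABLE
    # monotone missing tail = maximal trailing run of missing
    start = V
    while start > 0 and not mask[start - 1]:
        start -= 1
    tail_len = V - start
    if tail_len <= 1:
        return PatternLabel.COMPLETER_QUASI
    if tail_len == 2:
        return PatternLabel.LATE_DROPOUT
    return PatternLabel.EARLY_DROPOUT


@pytest.mark.parametrize("V", [3, 4, 6])
def test_classify_pattern_matches_literal_rules(V):
    for bits in range(2**V):
        mask = [(bits >> j) & 1 == 1 for j in range(V)]
        assert et.classify_pattern(mask) == literal_pattern_rules(mask), mask


@pytest.mark.parametrize(
    "mask,expected",
    [
        ([1, 1, 1, 1, 1, 1], PatternLabel.COMPLETER_QUASI),
        ([1, 1, 1, 1, 0, 0], PatternLabel.LATE_DROPOUT),
        ([1, 0, 0, 0, 0, 0], PatternLabel.EARLY_DROPOUT),
        ([1, 0, 1, 1, 0, 1], PatternLabel.COMPLETER_QUASI),
        ([1, 1, 1, 1, 1, 0], PatternLabel.COMPLETER_QUASI),
        ([0, 0, 0, 0, 0, 0], PatternLabel.UNCLASSIFIABLE),
    ],
)
def test_classify_pattern_reference_cases(mask, expected):
    assert et.classify_pattern(np.array(mask, dtype=bool)) == expected


def test_trailing_run():
    assert trailing_missing_run([True, False, False]) == 2
    assert trailing_missing_run([True, True]) == 0


# ---------------------------------------------------------------------------
# CSV round-trip
# ---------------------------------------------------------------------------


@st.composite
def trial_datasets(draw):
    V = draw(st.integers(3, 6))
    n = draw(st.integers(2, 8))
    sched = et.VisitSchedule(V)
    subs = []
    arms = ["placebo", "active"]
    for i in range(n):
        arm = arms[i % 2]
        baseline = draw(st.floats(10, 50, allow_nan=False))
        disc = draw(st.one_of(st.none(), st.integers(1, V)))
        outcomes = []
        for j in range(1, V + 1):
            if disc is not None and j > disc:
                outcomes.append(np.nan)
            elif draw(st.booleans()):
                outcomes.append(draw(st.floats(0, 60, allow_nan=False)))
            else:
                outcomes.append(np.nan)
        reason = draw(st.sampled_from(["AE", "LoE", "drug_unrelated"])) if disc else "none"
        subs.append(et.SubjectRecord(f"s{i}", arm, baseline, outcomes, reason, disc))
    return et.TrialDataset(sched, subs, "placebo")


@settings(max_examples=25, deadline=None, derandomize=True)
@given(trial_datasets())
def test_csv_round_trip_identity(tmp_path_factory, dataset):
    path = tmp_path_factory.mktemp("csv") / "trial.csv"
    et.write_trial_csv(dataset, path)
    back = et.read_trial_csv(path, dataset.reference_arm)
    assert back.schedule.n_visits == dataset.schedule.n_visits
    assert len(back.subjects) == len(dataset.subjects)
    for a, b in zip(dataset.subjects, back.subjects):
        assert a.subject_id == b.subject_id
        assert a.arm == b.arm
        assert a.baseline == b.baseline  # bit-exact
        np.testing.assert_array_equal(a.outcomes, b.outcomes)
        assert a.disc_reason == b.disc_reason
        assert a.disc_visit == b.disc_visit


def test_round_trip_empty_dataset(tmp_path):
    ds = et.TrialDataset(et.VisitSchedule(3), [], "placebo")
    path = tmp_path / "empty.csv"
    et.write_trial_csv(ds, path)
    back = et.read_trial_csv(path, "placebo")
    assert back.n_subjects == 0


def test_read_rejects_missing_column(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("subject_id,arm,baseline,visit,score\n")
    with pytest.raises(et.TrialValidationError, match="missing required column"):
        et.read_trial_csv(path, "placebo")


def test_read_rejects_out_of_range_score(tmp_path, tiny_dataset):
    df = tiny_dataset.to_frame()
    df.loc[0, "score"] = 63.0
    path = tmp_path / "bad.csv"
    df.to_csv(path, index=False)
    with pytest.raises(et.TrialValidationError, match="outside"):
        et.read_trial_csv(path, "placebo")


def test_read_rejects_monotone_violation(tmp_path, tiny_dataset):
    df = tiny_dataset.to_frame()
    # subject a2 discontinued at visit 3; observe visit 5 anyway
    row = (df.subject_id == "a2") & (df.visit == 5)
    df.loc[row, "score"] = 20.0
    path = tmp_path / "bad.csv"
    df.to_csv(path, index=False)
    with pytest.raises(et.TrialValidationError, match="a2"):
        et.read_trial_csv(path, "placebo")


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


def test_missingness_summary_arithmetic():
    sched = et.VisitSchedule(2)
    subs = [
        et.SubjectRecord("x", "placebo", 30, [20.0, 19.0]),
        et.SubjectRecord("y", "active", 30, [21.0, np.nan], "LoE", 1),
    ]
    ds = et.TrialDataset(sched, subs, "placebo")
    summ = et.missingness_summary(ds)
    assert summ.missing_fraction == pytest.approx(0.25)
    assert summ.mask_matrix.shape == (2, 2)
    per = summ.per_arm_visit
    assert per.loc[(per.arm == "active") & (per.visit == 2), "n_missing"].item() == 1


def test_missingness_invariant_to_subject_order(small_trial):
    ds, _ = small_trial
    frac = et.missingness_summary(ds).missing_fraction
    reordered = et.TrialDataset(
        ds.schedule, list(reversed(ds.subjects)), ds.reference_arm
    )
    assert et.missingness_summary(reordered).missing_fraction == frac


def test_missingness_matches_generator_truth(small_trial):
    ds, truth = small_trial
    Y = ds.outcome_matrix()
    expected = float(np.isnan(Y).sum() / Y.size)
    assert et.missingness_summary(ds).missing_fraction == pytest.approx(expected)


def test_ie_table_counts_and_percentages():
    # 88 randomized, 18 placebo LoE discontinuations -> 18 (20.5%)
    sched = et.VisitSchedule(6)
    subs = []
    for i in range(44):
        out = [20.0] * 6
        if i < 18:
            subs.append(
                et.SubjectRecord(f"p{i}", "placebo", 30, [20.0, 20.0, np.nan,
                                                          np.nan, np.nan, np.nan],
                                 "LoE", 2)
            )
        else:
            subs.append(et.SubjectRecord(f"p{i}", "placebo", 30, out))
    for i in range(44):
        subs.append(et.SubjectRecord(f"m{i}", "active", 30, [18.0] * 6))
    ds = et.TrialDataset(sched, subs, "placebo")
    tbl = et.ie_table(ds)
    cell = tbl[(tbl.arm == "placebo") & (tbl.reason == "LoE")]
    assert cell.n.item() == 18
    assert cell.pct_of_trial_n.item() == pytest.approx(20.5)
    # structural zeros retained, counts bounded by arm N
    assert (tbl.n >= 0).all()
    assert set(tbl.reason) >= {"AE", "LoE", "efficacy"}
    assert tbl.groupby("arm").n.sum().le(44).all()


def test_ie_table_all_zero_without_discontinuations(complete_trial):
    ds, _ = complete_trial
    tbl = et.ie_table(ds)
    assert (tbl.n == 0).all()


def test_schedule_invariants():
    with pytest.raises(et.TrialValidationError):
        et.VisitSchedule(1)
    with pytest.raises(et.TrialValidationError):
        et.VisitSchedule(3, {1: 1, 2: 3, 3: 2})
    s = et.VisitSchedule(3, {1: 1, 2: 2, 3: 6})
    assert s.last_visit == 3
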
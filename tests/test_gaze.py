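"""Eye-tracking measures: FFD/GD/GmF, trimming, exclusions."""

import math

import numpy as np
import pandas as pd
import pytest

from morphgaze.gaze import (
    FixationRecord, TrialRecord, compute_measures_exp1,
    compute_measures_exp2, exclude_error_and_subjects, measures_table,
    read_fixation_report, split_by_length, trim_outliers,
    write_fixation_report,
)


def _fix(area, onset, dur, idx, off=math.nan):
    return FixationRecord("s1", "t1", idx, area, onset, dur, off)


def _trial(fixes, **kw):
    return TrialRecord(subject="s1", item="w1", fixations=fixes, **kw)


class TestExp1Measures:
    def test_two_fixations(self):
        row = compute_measures_exp1(
            _trial([_fix(1, 0, 200, 1), _fix(1, 200, 150, 2)])
        )
        assert (row["FFD"], row["GD"], row["GmF"]) == (200, 350, 150)

    def test_single_fixation_gmf_missing(self):
        row = compute_measures_exp1(_trial([_fix(1, 0, 250, 1)]))
        assert (row["FFD"], row["GD"]) == (250, 250)
        assert math.isnan(row["GmF"])

    def test_three_fixations_sum(self):
        row = compute_measures_exp1(
            _trial([_fix(1, 0, 100, 1), _fix(1, 100, 100, 2),
                    _fix(1, 200, 100, 3)])
        )
        assert (row["FFD"], row["GD"], row["GmF"]) == (100, 300, 200)

    def test_no_fixation_excluded(self):
        row = compute_measures_exp1(_trial([]))
        assert row["excluded"] and row["exclude_reason"] == "no-fixation"


class TestExp2Measures:
    def test_first_run_excludes_refixations(self):
        """A regression back to the target after leaving it does not count."""
        t = _trial(
            [_fix(3, 0, 180, 1), _fix(3, 180, 120, 2), _fix(4, 300, 200, 3),
             _fix(3, 500, 90, 4)],
            row_position=3,
        )
        row = compute_measures_exp2(t, 3)
        assert (row["FFD"], row["GD"], row["GmF"]) == (180, 300, 120)

    def test_launch_site_letter_distance(self):
        t = _trial(
            [_fix(2, 0, 150, 1, off=-3.0), _fix(3, 150, 200, 2, off=1.0)],
            row_position=3,
        )
        row = compute_measures_exp2(t, 3)
        assert row["launch_site"] == 3.0

    def test_single_first_run_fixation_gmf_missing(self):
        t = _trial([_fix(3, 0, 210, 1), _fix(4, 210, 180, 2)],
                   row_position=3)
        row = compute_measures_exp2(t, 3)
        assert math.isnan(row["GmF"]) and row["GD"] == 210

    def test_skipped_target_excluded(self):
        t = _trial([_fix(2, 0, 150, 1), _fix(4, 150, 150, 2)],
                   row_position=3)
        row = compute_measures_exp2(t, 3)
        assert row["excluded"] and row["exclude_reason"] == "skipped"

    def test_first_run_gd_never_exceeds_exp1_gd(self):
        """All-fixation GD includes refixations the first run drops."""
        fixes = [_fix(1, 0, 100, 1), _fix(2, 100, 60, 2), _fix(1, 160, 80, 3)]
        gd_all = compute_measures_exp1(_trial(fixes))["GD"]
        gd_run = compute_measures_exp2(_trial(fixes, row_position=1), 1)["GD"]
        assert gd_run <= gd_all


def _table(values, subject="s1", measure="rt_ms"):
    rows = []
    for i, v in enumerate(values):
        rows.append({
            "subject": subject, "item": f"w{i}", "FFD": 100.0, "GD": 200.0,
            "GmF": 100.0, "presentation_order": i, "launch_site": math.nan,
            "row_position": None, "rt_ms": math.nan,
            "response_correct": None, "list_id": None,
            "excluded": False, "exclude_reason": "",
        })
        rows[-1][measure] = v
    return pd.DataFrame(rows)


class TestTrimming:
    def test_extreme_value_trimmed(self):
        # hand check: mean 550, sample SD 223.6, bound 1220.8 < 1500
        vals = [500.0] * 19 + [1500.0]
        m, sd = np.mean(vals), np.std(vals, ddof=1)
        assert 1500.0 > m + 3 * sd  # the fixture really is an outlier
        out = trim_outliers(_table(vals), "rt_ms", 3.0)
        assert out["excluded"].sum() == 1
        assert out.loc[out["excluded"], "exclude_reason"].item() == "outlier"

    def test_identical_rows_kept(self):
        out = trim_outliers(_table([500.0] * 10), "rt_ms", 3.0)
        assert out["excluded"].sum() == 0

    def test_infinite_k_is_identity(self):
        vals = list(np.linspace(100, 2000, 12))
        out = trim_outliers(_table(vals), "rt_ms", math.inf)
        assert out["excluded"].sum() == 0

    def test_single_pass_contract(self):
        """Bounds come from the input's included rows, once: a value that
        only becomes an outlier after the first removal survives the call."""
        vals = [500.0] * 19 + [1500.0, 1100.0]
        once = trim_outliers(_table(vals), "rt_ms", 3.0)
        assert once["excluded"].sum() == 1  # only the 1500 ms row
        # a second call recomputes bounds on the trimmed rows and now
        # catches the 1100 ms row -- proof the first call did not iterate
        twice = trim_outliers(once, "rt_ms", 3.0)
        assert twice["excluded"].sum() == 2

    def test_fewer_than_two_rows_untrimmed(self):
        out = trim_outliers(_table([500.0]), "rt_ms", 3.0)
        assert out["excluded"].sum() == 0

    def test_unknown_measure_rejected(self):
        with pytest.raises(ValueError):
            trim_outliers(_table([1.0]), "nope")


class TestSubjectExclusion:
    def _resp_table(self, n_err, n=100, subject="s1"):
        df = _table([500.0] * n, subject=subject)
        df["response_correct"] = [False] * n_err + [True] * (n - n_err)
        return df

    def test_over_threshold_subject_excluded(self):
        out = exclude_error_and_subjects(self._resp_table(16))
        assert out["excluded"].all()

    def test_at_threshold_subject_retained(self):
        """The criterion is strict: exactly 15% stays in."""
        out = exclude_error_and_subjects(self._resp_table(15))
        # only the error trials themselves are dropped
        assert out["excluded"].sum() == 15
        assert set(out.loc[out["excluded"], "exclude_reason"]) == {"error"}

    def test_error_trials_of_retained_subject_dropped(self):
        out = exclude_error_and_subjects(self._resp_table(3))
        assert out["excluded"].sum() == 3


class TestLengthSplit:
    def test_eight_letter_boundary(self):
        short, long_ = split_by_length(["abcd", "a" * 8, "b" * 9, "c" * 16])
        assert short == {"abcd", "a" * 8}
        assert long_ == {"b" * 9, "c" * 16}

    def test_all_short_leaves_long_empty(self):
        short, long_ = split_by_length(["a" * 8] * 3)
        assert long_ == set()

    def test_zero_threshold_all_long(self):
        short, long_ = split_by_length(["ab", "c"], threshold_letters=0)
        assert short == set()


class TestReportIO:
    def test_roundtrip(self, tmp_path):
        trials = [
            TrialRecord(
                subject="s1", item="talo",
                fixations=[_fix(1, 0, 200, 1), _fix(1, 200, 150, 2)],
                presentation_order=4, response_correct=True, rt_ms=512.0,
            ),
            TrialRecord(
                subject="s2", item="auto",
                fixations=[_fix(2, 0, 150, 1, off=-2.0),
                           _fix(3, 150, 210, 2, off=1.0)],
                presentation_order=1, list_id="list1", row_position=3,
            ),
        ]
        path = tmp_path / "fix.tsv"
        write_fixation_report(trials, path)
        again = read_fixation_report(path)
        assert len(again) == 2
        t2 = next(t for t in again if t.subject == "s2")
        assert t2.row_position == 3 and t2.list_id == "list1"
        assert [f.duration for f in t2.fixations] == [150, 210]

    def test_measures_table_gmf_identity(self):
        trials = [
            _trial([_fix(1, 0, 200, 1), _fix(1, 200, 150, 2)]),
            _trial([_fix(1, 0, 250, 1)]),
        ]
        df = measures_table(trials, "exp1")
        both = df[df["GmF"].notna()]
        assert (both["GmF"] == both["GD"] - both["FFD"]).all()
        assert df["GmF"].isna().sum() == 1
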
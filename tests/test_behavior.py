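"""Activity metrics, bout detection, scoring and response rates."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from blastdose.behavior import (
    ActivityTrace,
    FinPokeRecord,
    SeizureScore,
    classify_dead,
    detect_high_activity_bouts,
    detect_inactivity,
    high_activity_threshold,
    larva_metrics,
    mean_activity,
    read_activity_csv,
    response_rate,
    seizure_proportions,
    write_activity_csv,
)

from conftest import brute_force_runs


def make_trace(activity, bin_s=1.0, larva_id="L1", group="g"):
    activity = np.asarray(activity, dtype=float)
    edges = np.arange(len(activity) + 1) * bin_s
    return ActivityTrace(
        larva_id=larva_id,
        group=group,
        well="A1",
        t_start_s=edges[:-1],
        t_end_s=edges[1:],
        activity=activity,
    )


class TestMeanActivity:
    def test_constant(self):
        assert mean_activity(make_trace([2.0] * 30)) == 2.0

    def test_two_bins(self):
        assert mean_activity(make_trace([0.0, 4.0])) == 2.0

    @given(values=st.lists(st.floats(0, 100), min_size=1, max_size=200))
    def test_equals_sum_over_n(self, values):
        assert mean_activity(make_trace(values)) == pytest.approx(
            sum(values) / len(values), rel=1e-9, abs=1e-9
        )


class TestHighActivityThreshold:
    def test_64_percent_of_group_max(self):
        controls = [make_trace([1, 10, 2]), make_trace([8, 3, 1])]
        assert high_activity_threshold(controls) == pytest.approx(6.4)

    def test_all_zero_controls_warn(self):
        with pytest.warns(UserWarning, match="zero activity"):
            assert high_activity_threshold([make_trace([0, 0, 0])]) == 0.0

    def test_empty_control_set_rejected(self):
        with pytest.raises(ValueError):
            high_activity_threshold([])

    @given(scale=st.floats(0.1, 10))
    def test_scales_linearly(self, scale):
        controls = [make_trace([1, 5, 3])]
        scaled = [make_trace([scale * 1, scale * 5, scale * 3])]
        assert high_activity_threshold(scaled) == pytest.approx(
            scale * high_activity_threshold(controls)
        )


class TestHighActivityBouts:
    def test_no_bin_above(self):
        assert detect_high_activity_bouts(make_trace([1, 2, 3]), 6.4) == []

    def test_single_run(self):
        bouts = detect_high_activity_bouts(make_trace([1, 9, 9, 1]), 6.4)
        assert len(bouts) == 1
        assert (bouts[0].start_s, bouts[0].end_s) == (1.0, 3.0)

    def test_all_above_is_one_bout(self):
        trace = make_trace([9.0] * 10)
        bouts = detect_high_activity_bouts(trace, 6.4)
        assert len(bouts) == 1
        assert bouts[0].duration_s == trace.duration_s

    @given(st.data())
    def test_matches_run_length_oracle(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        activity = rng.uniform(0, 10, size=rng.integers(1, 120))
        threshold = rng.uniform(0, 10)
        bouts = detect_high_activity_bouts(make_trace(activity), threshold)
        oracle = brute_force_runs(activity > threshold)
        assert [(b.start_s, b.end_s) for b in bouts] == [
            (float(i), float(j + 1)) for i, j in oracle
        ]


class TestInactivity:
    def test_90s_run_counts(self):
        activity = [1.0] * 10 + [0.0] * 90 + [1.0] * 10
        bouts, total = detect_inactivity(make_trace(activity))
        assert len(bouts) == 1 and total == 90.0

    def test_30s_run_below_cutoff(self):
        activity = [1.0] * 10 + [0.0] * 30 + [1.0] * 10
        bouts, total = detect_inactivity(make_trace(activity))
        assert bouts == [] and total == 0.0

    def test_exactly_60s_counts(self):
        # boundary: the one-minute rule is inclusive ("1 min or more")
        activity = [1.0] + [0.0] * 60 + [1.0]
        bouts, total = detect_inactivity(make_trace(activity))
        assert total == 60.0

    def test_59s_does_not_count(self):
        activity = [1.0] + [0.0] * 59 + [1.0]
        _, total = detect_inactivity(make_trace(activity))
        assert total == 0.0

    def test_two_runs_sum(self):
        activity = [0.0] * 60 + [1.0] * 5 + [0.0] * 120 + [1.0] * 5
        bouts, total = detect_inactivity(make_trace(activity))
        assert len(bouts) == 2 and total == 180.0

    @given(st.data())
    def test_matches_run_length_oracle(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        # sparse activity so minute-scale zero runs actually occur
        activity = rng.choice([0.0, 0.0, 0.0, 1.0], size=300)
        bouts, total = detect_inactivity(make_trace(activity), min_duration_s=60)
        oracle = [
            (i, j)
            for i, j in brute_force_runs(activity <= 0)
            if (j + 1 - i) >= 60
        ]
        assert [(b.start_s, b.end_s) for b in bouts] == [
            (float(i), float(j + 1)) for i, j in oracle
        ]
        assert total == sum(j + 1 - i for i, j in oracle)

    def test_total_bounded_and_monotone(self):
        rng = np.random.default_rng(3)
        activity = rng.choice([0.0, 0.0, 1.0], size=400)
        trace = make_trace(activity)
        _, total = detect_inactivity(trace)
        assert total <= trace.duration_s
        # adding activity to any bin never increases total inactive time
        for idx in np.flatnonzero(activity == 0)[::37]:
            bumped = activity.copy()
            bumped[idx] = 5.0
            _, total_bumped = detect_inactivity(make_trace(bumped))
            assert total_bumped <= total


class TestDeadAndMetrics:
    def test_all_zero_is_candidate_dead(self):
        assert classify_dead(make_trace([0.0] * 100)) is True

    def test_single_nonzero_is_alive(self):
        assert classify_dead(make_trace([0.0] * 99 + [0.1])) is False

    def test_metrics_table_counts_dead(self):
        traces = [
            make_trace([1, 2, 3], larva_id="c1", group="control"),
            make_trace([0, 0, 0], larva_id="t1", group="tbi"),
            make_trace([5, 0, 1], larva_id="t2", group="tbi"),
        ]
        metrics = larva_metrics(traces, control_group="control")
        assert metrics["candidate_dead"].sum() == 1
        assert len(metrics) == 3


class TestResponseRate:
    def _records(self, n, responded, timepoint=30):
        return [
            FinPokeRecord(f"L{i}", "g", timepoint, i < responded) for i in range(n)
        ]

    def test_all_respond(self):
        assert response_rate(self._records(10, 10), 30) == 1.0

    def test_none_respond(self):
        assert response_rate(self._records(10, 0), 30) == 0.0

    def test_counting(self):
        assert response_rate(self._records(13, 8), 30) == pytest.approx(8 / 13)

    def test_unverified_heartbeat_excluded(self):
        records = self._records(10, 5) + [
            FinPokeRecord("dead", "g", 30, False, heartbeat_verified=False)
        ]
        assert response_rate(records, 30) == pytest.approx(0.5)

    def test_missing_timepoint_rejected(self):
        with pytest.raises(ValueError, match="15"):
            response_rate(self._records(5, 3, timepoint=30), 15)

    def test_off_grid_timepoint_rejected(self):
        with pytest.raises(ValueError):
            FinPokeRecord("L1", "g", 7, True)


class TestSeizureProportions:
    def test_all_none(self):
        scores = [SeizureScore(f"L{i}", "none") for i in range(5)]
        assert seizure_proportions(scores) == {
            "none": 1.0,
            "stage_I": 0.0,
            "stage_II_III": 0.0,
        }

    def test_counting_24_larvae(self):
        scores = (
            [SeizureScore(f"a{i}", "none") for i in range(12)]
            + [SeizureScore(f"b{i}", "stage_I") for i in range(6)]
            + [SeizureScore(f"c{i}", "stage_II_III") for i in range(6)]
        )
        assert seizure_proportions(scores) == {
            "none": 0.5,
            "stage_I": 0.25,
            "stage_II_III": 0.25,
        }

    @given(st.data())
    def test_sums_to_one_and_permutation_invariant(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 1000)))
        stages = rng.choice(["none", "stage_I", "stage_II_III"], size=20)
        scores = [SeizureScore(f"L{i}", s) for i, s in enumerate(stages)]
        props = seizure_proportions(scores)
        assert sum(props.values()) == pytest.approx(1.0)
        shuffled = list(scores)
        rng.shuffle(shuffled)
        assert seizure_proportions(shuffled) == props

    def test_duplicate_larva_rejected(self):
        scores = [SeizureScore("L1", "none"), SeizureScore("L1", "stage_I")]
        with pytest.raises(ValueError, match="L1"):
            seizure_proportions(scores)


class TestActivityCsv:
    def test_round_trip(self, tmp_path):
        traces = [
            make_trace([1, 2, 0], larva_id="a", group="control"),
            make_trace([0, 0, 5], larva_id="b", group="tbi"),
        ]
        path = tmp_path / "activity.csv"
        write_activity_csv(traces, path)
        back = read_activity_csv(path)
        assert [tr.larva_id for tr in back] == ["a", "b"]
        np.testing.assert_allclose(back[1].activity, [0, 0, 5])

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("larva_id,activity\nx,1\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_activity_csv(path)
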
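"""Sleep, mobility, activity and expression feature extraction."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from moodsense.features import (
    FEATURE_NAMES,
    FeatureConfig,
    OffInterval,
    aggregate_expression,
    assemble_features,
    cluster_gps,
    daily_activity_time,
    daily_usage,
    estimate_daily_sleep,
    feature_matrix,
    location_entropy,
    location_variance,
    screen_off_intervals,
    sleep_feature_block,
    stat_summary,
    stub_embedder,
)
from moodsense.sensor_io import assemble_bundle, dedupe_screen_events
from moodsense.types import (
    ActivityClass,
    ActivityTransitionEvent,
    FaceEmbeddingRecord,
    GpsFix,
    Transition,
)

from conftest import canonical_labels, dbscan_oracle, screen, t


def gps(*points: tuple[int, float, float, float]) -> list[GpsFix]:
    return [GpsFix("p1", t(d, h), lat, lon) for d, h, lat, lon in points]


def activity(*events: tuple[int, float, str, str]) -> list[ActivityTransitionEvent]:
    return [
        ActivityTransitionEvent("p1", t(d, h), ActivityClass(c), Transition(tr))
        for d, h, c, tr in events
    ]


class TestScreenOffIntervals:
    def test_single_night_interval(self):
        events = screen("p1", (0, 8, "ON"), (0, 23, "OFF"), (1, 7, "ON"))
        intervals = screen_off_intervals(events)
        assert len(intervals) == 1
        assert intervals[0].hours == pytest.approx(8.0)

    def test_trailing_off_closed_at_window_end_and_flagged(self):
        events = screen("p1", (0, 22, "ON"), (0, 23, "OFF"))
        intervals = screen_off_intervals(events, window_end=t(1, 9))
        assert len(intervals) == 1
        assert intervals[0].unterminated
        assert intervals[0].hours == pytest.approx(10.0)

    def test_off_time_complements_on_time(self):
        # 3 OFF/ON pairs; window 0:00 -> 24:00 with ON spans 8-10, 12-14, 16-18.
        events = screen(
            "p1",
            (0, 0, "OFF"), (0, 8, "ON"), (0, 10, "OFF"), (0, 12, "ON"),
            (0, 14, "OFF"), (0, 16, "ON"), (0, 18, "OFF"),
        )
        intervals = screen_off_intervals(events, window_end=t(1, 0))
        total_off = sum(iv.hours for iv in intervals)
        assert len(intervals) == 4
        assert total_off == pytest.approx(24.0 - 6.0)


class TestDailySleep:
    def test_overnight_interval_attributed_to_morning_date(self):
        sleep = estimate_daily_sleep([OffInterval(t(0, 23), t(1, 7))])
        assert sleep == {t(1).date(): pytest.approx(8.0)}

    def test_afternoon_only_candidate_discarded(self):
        sleep = estimate_daily_sleep([OffInterval(t(0, 13), t(0, 16))])
        assert sleep == {}

    def test_interval_spanning_past_afternoon_survives(self):
        sleep = estimate_daily_sleep([OffInterval(t(0, 13), t(0, 20))])
        assert len(sleep) == 1

    def test_over_24h_candidate_discarded(self):
        sleep = estimate_daily_sleep([OffInterval(t(0, 1), t(1, 3))])  # 26 h
        assert sleep == {}

    def test_truncated_boundary_days_dropped_with_window(self):
        ivs = [OffInterval(t(0, 9), t(0, 11)), OffInterval(t(0, 23), t(1, 7))]
        sleep = estimate_daily_sleep(ivs, window=(t(0, 0), t(1, 12)))
        assert list(sleep) == [t(1).date()]  # morning gap of day 0 is boundary-truncated


class TestDailyUsage:
    def test_simple_on_interval(self):
        events = screen("p1", (0, 10, "ON"), (0, 12, "OFF"))
        assert daily_usage(events) == {t(0).date(): pytest.approx(2.0)}

    def test_midnight_spanning_interval_split(self):
        events = screen("p1", (0, 23, "ON"), (1, 1, "OFF"))
        usage = daily_usage(events)
        assert usage[t(0).date()] == pytest.approx(1.0)
        assert usage[t(1).date()] == pytest.approx(1.0)

    def test_no_on_intervals_is_zero_over_window(self):
        usage = daily_usage([], window=(t(0), t(1)))
        assert set(usage.values()) == {0.0}


class TestStatSummary:
    def test_constant_series(self):
        s = stat_summary([2.0, 2.0, 2.0])
        assert s.as_array().tolist() == [2, 2, 2, 0, 2, 2, 2]

    def test_linear_interpolation_quartiles(self):
        s = stat_summary([1.0, 2.0, 3.0, 4.0])
        assert s.q2 == pytest.approx(2.5)
        assert s.mean == pytest.approx(2.5)
        assert s.q1 == pytest.approx(1.75)
        assert s.sd == pytest.approx(np.std([1, 2, 3, 4], ddof=1))

    def test_empty_series_signals_missing_group(self):
        assert stat_summary([]) is None

    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=30), st.randoms())
    def test_permutation_invariance_and_ordering(self, values, rnd):
        a = stat_summary(values)
        shuffled = values[:]
        rnd.shuffle(shuffled)
        b = stat_summary(shuffled)
        assert np.allclose(a.as_array(), b.as_array())
        assert a.minimum <= a.q1 <= a.q2 <= a.q3 <= a.maximum
        assert a.sd >= 0


class TestSleepBlock:
    def test_constant_schedule_yields_constant_stats(self):
        # 8 h sleep (23:00 -> 07:00 next day) and 4.5 h usage daily.
        days = 6
        evs = []
        for d in range(days):
            evs += screen(
                "p1",
                (d, 7, "ON"), (d, 9, "OFF"),
                (d, 12.5, "ON"), (d, 14.4, "OFF"),
                (d, 18, "ON"), (d, 18.5, "OFF"),
                (d, 22.9, "ON"), (d, 23, "OFF"),
            )
        bundle = assemble_bundle({"SCREEN_ONOFF": evs}, (t(0), t(days - 1, 23)))
        block = sleep_feature_block(bundle)
        sleep_stats, usage_stats = block[:7], block[7:]
        assert np.allclose(sleep_stats[[0, 1, 2, 4, 5, 6]], 8.0)
        assert sleep_stats[3] == pytest.approx(0.0)  # sd
        assert np.allclose(usage_stats[[0, 1, 2, 4, 5, 6]], 4.5)
        assert usage_stats[3] == pytest.approx(0.0)

    def test_redundant_same_state_events_do_not_change_features(self):
        evs = []
        for d in range(4):
            evs += screen("p1", (d, 8, "ON"), (d, 23, "OFF"))
        evs += screen("p1", (4, 7, "ON"))
        noisy = evs + screen("p1", (1, 9, "ON"), (2, 23.5, "OFF"))  # redundant states
        b1 = assemble_bundle({"SCREEN_ONOFF": evs}, (t(0), t(4, 12)))
        b2 = assemble_bundle({"SCREEN_ONOFF": dedupe_screen_events(noisy)}, (t(0), t(4, 12)))
        assert np.allclose(sleep_feature_block(b1), sleep_feature_block(b2))

    def test_empty_stream_is_missing(self):
        bundle = assemble_bundle({}, (t(0), t(1)))
        assert sleep_feature_block(bundle) is None


class TestClusterGps:
    def test_two_well_separated_clusters(self):
        fixes = gps(*[(0, h, 37.5, 127.0) for h in range(10)])
        fixes += gps(*[(1, h, 37.545, 127.0) for h in range(10)])  # ~5 km north
        labels = cluster_gps(fixes, eps_meters=300, min_samples=5)
        assert set(labels) == {0, 1}
        assert (labels == -1).sum() == 0

    def test_isolated_fixes_are_noise(self):
        fixes = gps(*[(0, h, 37.5 + 0.01 * i, 127.0) for i, h in enumerate(range(20))])
        labels = cluster_gps(fixes, eps_meters=300, min_samples=5)
        assert set(labels) == {-1}

    def test_matches_brute_force_oracle_on_random_instance(self):
        rng = np.random.default_rng(42)
        coords = np.column_stack(
            [37.5 + rng.normal(0, 0.01, 200), 127.0 + rng.normal(0, 0.01, 200)]
        )
        fixes = [GpsFix("p1", t(0, i * 0.1), la, lo) for i, (la, lo) in enumerate(coords)]
        labels = cluster_gps(fixes, eps_meters=300, min_samples=5)
        oracle = dbscan_oracle(coords, eps_m=300, min_samples=5)
        assert np.array_equal(canonical_labels(labels), canonical_labels(oracle))

    def test_translation_leaves_labels_unchanged(self):
        rng = np.random.default_rng(1)
        coords = np.column_stack(
            [37.5 + rng.normal(0, 0.005, 60), 127.0 + rng.normal(0, 0.005, 60)]
        )
        fixes = [GpsFix("p1", t(0, i * 0.1), la, lo) for i, (la, lo) in enumerate(coords)]
        shifted = [
            GpsFix("p1", f.timestamp, f.latitude + 1e-5, f.longitude + 1e-5) for f in fixes
        ]
        assert np.array_equal(cluster_gps(fixes, 300, 5), cluster_gps(shifted, 300, 5))


class TestLocationVariance:
    def test_log_identity_at_unit_variance(self):
        fixes = gps((0, 0, 0.0, 0.0), (0, 1, 0.0, 2.0))
        # population variances: lat 0, lon 1.0 -> log(1) = 0
        assert location_variance(fixes) == pytest.approx(0.0)

    def test_degenerate_single_place_hits_floor(self):
        fixes = gps((0, 0, 37.5, 127.0), (0, 1, 37.5, 127.0))
        assert location_variance(fixes) == pytest.approx(math.log(1e-12))

    def test_fewer_than_two_fixes_is_missing(self):
        assert location_variance(gps((0, 0, 37.5, 127.0))) is None

    def test_translation_invariance(self):
        fixes = gps(*[(0, h, 37.5 + 0.001 * h, 127.0 - 0.002 * h) for h in range(10)])
        shifted = [
            GpsFix("p1", f.timestamp, f.latitude + 0.7, f.longitude - 1.3) for f in fixes
        ]
        assert location_variance(shifted) == pytest.approx(location_variance(fixes), abs=1e-9)


class TestLocationEntropy:
    def test_uniform_two_clusters(self):
        assert location_entropy([0] * 50 + [1] * 50) == pytest.approx(math.log(2))

    def test_single_cluster_zero(self):
        assert location_entropy([0] * 10) == 0.0

    def test_three_quarters_split(self):
        expected = -(0.75 * math.log(0.75) + 0.25 * math.log(0.25))
        assert location_entropy([0] * 75 + [1] * 25) == pytest.approx(expected)

    def test_all_noise_is_missing(self):
        assert location_entropy([-1, -1, -1]) is None

    def test_noise_fixes_excluded_from_proportions(self):
        assert location_entropy([0, 0, 1, 1, -1, -1, -1]) == pytest.approx(math.log(2))

    @given(st.lists(st.integers(1, 200), min_size=1, max_size=8))
    def test_bounded_by_log_k_and_maximal_iff_uniform(self, counts):
        labels = [i for i, c in enumerate(counts) for _ in range(c)]
        h = location_entropy(labels)
        k = len(counts)
        assert -1e-12 <= h <= math.log(k) + 1e-12
        if len(set(counts)) == 1:  # uniform partition maximizes entropy
            assert h == pytest.approx(math.log(k) if k > 1 else 0.0)
        else:  # any non-uniform partition is strictly below the bound
            assert h < math.log(k) - 1e-12


class TestDailyActivity:
    def test_single_walking_hour(self):
        evs = activity((0, 9, "WALKING", "ENTER"), (0, 10, "WALKING", "EXIT"))
        assert daily_activity_time(evs) == pytest.approx(1.0)

    def test_cycling_excluded_but_day_observed(self):
        evs = activity((0, 16, "CYCLING", "ENTER"), (0, 16.5, "CYCLING", "EXIT"))
        assert daily_activity_time(evs) == pytest.approx(0.0)

    def test_mean_over_observed_days(self):
        evs = activity(
            (0, 9, "WALKING", "ENTER"), (0, 10, "WALKING", "EXIT"),
            (1, 9, "RUNNING", "ENTER"), (1, 12, "RUNNING", "EXIT"),
        )
        assert daily_activity_time(evs) == pytest.approx(2.0)

    def test_unmatched_enter_closed_at_window_end(self):
        evs = activity((0, 9, "WALKING", "ENTER"))
        assert daily_activity_time(evs, window_end=t(0, 11)) == pytest.approx(2.0)

    def test_no_events_missing(self):
        assert daily_activity_time([]) is None

    def test_stationary_included_by_default_config(self):
        evs = activity((0, 9, "STATIONARY", "ENTER"), (0, 11, "STATIONARY", "EXIT"))
        assert daily_activity_time(evs) == pytest.approx(2.0)
        locomotion = {ActivityClass.WALKING, ActivityClass.RUNNING,
                      ActivityClass.WALKING_OR_RUNNING}
        assert daily_activity_time(evs, included_classes=locomotion) == pytest.approx(0.0)


class TestExpression:
    def test_single_record_identity(self):
        v = tuple(float(i) for i in range(16))
        assert np.allclose(aggregate_expression([FaceEmbeddingRecord("p", t(0), v)]), v)

    def test_symmetric_records_cancel(self):
        v = tuple(float(i) for i in range(16))
        neg = tuple(-x for x in v)
        recs = [FaceEmbeddingRecord("p", t(0), v), FaceEmbeddingRecord("p", t(1), neg)]
        assert np.allclose(aggregate_expression(recs), 0.0)

    def test_elementwise_mean(self):
        rows = np.arange(48, dtype=float).reshape(3, 16)
        recs = [FaceEmbeddingRecord("p", t(i), tuple(r)) for i, r in enumerate(rows)]
        assert np.allclose(aggregate_expression(recs), rows.mean(axis=0))

    def test_empty_is_missing(self):
        assert aggregate_expression([]) is None

    def test_stub_embedder_deterministic_unit_norm(self):
        a, b = stub_embedder("img1"), stub_embedder("img1")
        assert np.allclose(a, b)
        assert np.linalg.norm(a) == pytest.approx(1.0)
        assert not np.allclose(a, stub_embedder("img2"))


class TestAssembly:
    def test_complete_bundle_yields_33_observed_features(self, small_cohort):
        bundles, _ = small_cohort
        fv = assemble_features(bundles[0])
        assert fv.values.shape == (33,)
        assert not np.isnan(fv.values).any()
        assert set(fv.provenance.values()) == {"observed"}
        assert len(FEATURE_NAMES) == 33

    def test_missing_gps_drop_vs_keep(self, small_cohort):
        bundles, _ = small_cohort
        import copy

        crippled = copy.copy(bundles[0])
        crippled.gps_fixes = []
        fv = assemble_features(crippled)
        assert fv.provenance["mobility"] == "missing"
        assert np.isnan(fv.values[14:16]).all()
        matrix, _ = feature_matrix([crippled, bundles[1]], missing_policy="drop")
        assert list(matrix.index) == [bundles[1].participant_id]
        kept, prov = feature_matrix([crippled, bundles[1]], missing_policy="keep")
        assert kept.shape == (2, 33)
        assert prov.loc[crippled.participant_id, "mobility"] == "missing"

    def test_cohort_matrix_shape(self, small_cohort):
        bundles, _ = small_cohort
        matrix, prov = feature_matrix(bundles)
        assert matrix.shape == (len(bundles), 33)
        assert list(matrix.columns) == FEATURE_NAMES
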
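"""Sleep scoring, bout detection, death calling and daily summaries."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from flychrono.sleep_activity import (
    call_death,
    daily_summaries,
    find_bouts,
    score_sleep,
    wake_activity,
)
from flychrono.synthetic_data import GenotypeSimConfig, simulate_cohort

BINS_PER_DAY = 288


def naive_bouts(asleep):
    """Bin-by-bin scan oracle for maximal runs of True."""
    bouts, start = [], None
    for i, v in enumerate(asleep):
        if v and start is None:
            start = i
        elif not v and start is not None:
            bouts.append((start, i - start))
            start = None
    if start is not None:
        bouts.append((start, len(asleep) - start))
    return bouts


class TestScoreSleep:
    def test_single_zero_bin_is_sleep(self, make_recording):
        rec = make_recording([0, 3, 0, 0])
        assert score_sleep(rec).asleep.tolist() == [True, False, True, True]

    def test_all_active_no_sleep(self, make_recording):
        rec = make_recording([2, 1, 5])
        assert not score_sleep(rec).asleep.any()

    def test_masked_bins_never_asleep(self, make_recording):
        rec = make_recording([0, 0, 0], masked=[False, True, False])
        assert score_sleep(rec).asleep.tolist() == [True, False, True]

    def test_post_death_bins_never_asleep(self, make_recording):
        rec = make_recording([0, 0, 0, 0])
        assert score_sleep(rec, death_bin=2).asleep.tolist() == [True, True, False, False]

    def test_threshold_in_whole_bins_required(self, make_recording):
        with pytest.raises(ValueError, match="whole"):
            score_sleep(make_recording([0, 0]), sleep_threshold_min=7)

    def test_ten_minute_threshold_drops_lone_zero_bins(self, make_recording):
        rec = make_recording([0, 3, 0, 0])
        assert score_sleep(rec, sleep_threshold_min=10).asleep.tolist() == [
            False, False, True, True,
        ]

    @given(st.lists(st.integers(0, 3), min_size=1, max_size=100))
    def test_lower_threshold_never_decreases_sleep(self, make_recording, counts):
        rec = make_recording(counts)
        s1 = score_sleep(rec, sleep_threshold_min=5).asleep.sum()
        s2 = score_sleep(rec, sleep_threshold_min=10).asleep.sum()
        assert s1 >= s2


class TestFindBouts:
    @pytest.mark.parametrize(
        "series, expected",
        [
            ([True, True, False, True], [(0, 2), (3, 1)]),
            ([False, False], []),
            ([True] * 7, [(0, 7)]),
            ([], []),
        ],
    )
    def test_examples(self, series, expected):
        assert find_bouts(series) == expected

    @given(st.lists(st.booleans(), min_size=1, max_size=200))
    def test_matches_naive_scan(self, series):
        assert find_bouts(series) == naive_bouts(series)


class TestCallDeath:
    def _record_with_silent_tail(self, make_recording, tail_hours, total_days=30):
        n = total_days * BINS_PER_DAY
        tail = int(tail_hours * 12)  # 12 five-min bins per hour
        counts = np.ones(n, dtype=int)
        counts[n - tail :] = 0
        return make_recording(counts), n - tail

    def test_25h_terminal_silence_is_death(self, make_recording):
        rec, onset = self._record_with_silent_tail(make_recording, 25)
        vit = call_death(rec)
        assert vit.dead
        assert vit.death_bin == onset
        assert vit.lifespan_days == pytest.approx(onset * 5 / 1440)

    def test_23h_terminal_silence_is_censored(self, make_recording):
        rec, _ = self._record_with_silent_tail(make_recording, 23)
        vit = call_death(rec)
        assert not vit.dead
        assert vit.lifespan_days == 30.0

    def test_exactly_24h_not_death(self, make_recording):
        # the rule is strictly more than 24 hours of silence
        rec, _ = self._record_with_silent_tail(make_recording, 24)
        assert not call_death(rec).dead

    def test_mid_record_silence_not_death(self, make_recording):
        counts = np.ones(30 * BINS_PER_DAY, dtype=int)
        counts[1000:1400] = 0  # >24h but not terminal
        assert not call_death(make_recording(counts)).dead

    def test_idempotent_under_truncation_at_death(self, make_recording):
        rec, onset = self._record_with_silent_tail(make_recording, 30)
        vit = call_death(rec)
        truncated = make_recording(rec.counts[: vit.death_bin + 350])
        vit2 = call_death(truncated)
        assert vit2.dead and vit2.death_bin == vit.death_bin

    def test_appending_activity_cancels_subthreshold_call(self, make_recording):
        rec, _ = self._record_with_silent_tail(make_recording, 23)
        revived = make_recording(np.r_[rec.counts, [2, 1]])
        assert not call_death(revived).dead

    def test_death_beyond_horizon_censored(self, make_recording):
        n = 40 * BINS_PER_DAY
        counts = np.ones(n, dtype=int)
        counts[35 * BINS_PER_DAY :] = 0  # dies day 35, horizon 30
        vit = call_death(make_recording(counts))
        assert not vit.dead and vit.lifespan_days == 30.0

    def test_all_zero_record_is_dead_on_arrival(self, make_recording):
        vit = call_death(make_recording(np.zeros(30 * BINS_PER_DAY, dtype=int)))
        assert vit.dead and vit.dead_on_arrival and vit.lifespan_days > 0

    def test_simulated_wakeforced_deaths_recovered(self, make_recording):
        cfg = GenotypeSimConfig(
            label="g", n_flies=16, lifespan_median_days=15.0,
            activity_template=np.full(288, 10.0), p_wake_to_sleep=0.0,
            p_sleep_to_wake=1.0, age_decline=1.0,
        )
        recs, truth = simulate_cohort(cfg, seed=7, n_days=31)
        for f, rec in enumerate(recs):
            tb = truth.death_bin[f]
            if tb < 0 or rec.n_bins - tb <= 289 or tb * 5 / 1440 > 30:
                continue
            vit = call_death(rec)
            assert vit.dead
            assert abs(vit.death_bin - tb) <= 1


class TestWakeActivity:
    def test_arithmetic_example(self, make_recording):
        rec = make_recording([10, 0, 5])
        wa = wake_activity(rec, score_sleep(rec))
        assert wa == pytest.approx(15 / 10)  # 15 counts over two awake bins

    def test_never_sleeping_equals_plain_rate(self, make_recording):
        counts = np.array([2, 4, 6, 8])
        rec = make_recording(counts)
        wa = wake_activity(rec, score_sleep(rec))
        assert wa == pytest.approx(counts.sum() / (5 * counts.size))

    def test_all_asleep_window_is_missing(self, make_recording):
        rec = make_recording([0, 0, 0])
        assert np.isnan(wake_activity(rec, score_sleep(rec)))


class TestDailySummaries:
    def _score(self, rec):
        vit = call_death(rec)
        return score_sleep(rec, death_bin=vit.death_bin), vit

    def test_constant_activity_day(self, make_recording):
        rec = make_recording(np.ones(2 * BINS_PER_DAY, dtype=int))
        df = daily_summaries(rec, *self._score(rec))
        assert len(df) == 2
        assert (df["total_counts"] == 288).all()
        assert (df["sleep_minutes"] == 0).all()
        assert df["age_class"].tolist() == ["young", "young"]

    def test_all_zero_living_day_splits_bout_at_zt12(self, make_recording):
        counts = np.ones(3 * BINS_PER_DAY, dtype=int)
        counts[BINS_PER_DAY : 2 * BINS_PER_DAY] = 0  # day 2 fully silent (<24 h + flanked)
        rec = make_recording(counts)
        df = daily_summaries(rec, *self._score(rec))
        day2 = df[df["day_index"] == 2].iloc[0]
        assert day2["sleep_minutes"] == 1440
        assert day2["n_sleep_bouts_day"] == 1
        assert day2["n_sleep_bouts_night"] == 1

    def test_death_day_and_beyond_excluded(self, make_recording):
        counts = np.ones(10 * BINS_PER_DAY, dtype=int)
        counts[int(4.5 * BINS_PER_DAY) :] = 0  # dies mid-day 5
        rec = make_recording(counts)
        df = daily_summaries(rec, *self._score(rec))
        assert df["day_index"].max() == 4

    def test_age_class_split_at_day_13(self, make_recording):
        rec = make_recording(np.ones(15 * BINS_PER_DAY, dtype=int))
        df = daily_summaries(rec, *self._score(rec))
        assert (df.loc[df["day_index"] <= 13, "age_class"] == "young").all()
        assert (df.loc[df["day_index"] > 13, "age_class"] == "old").all()

    def test_sleep_wake_conservation(self, make_recording):
        cfg = GenotypeSimConfig(label="g", n_flies=6)
        recs, _ = simulate_cohort(cfg, seed=9, n_days=10)
        for rec in recs:
            slp, vit = self._score(rec)
            df = daily_summaries(rec, slp, vit)
            for _, row in df.iterrows():
                wake_minutes = 5 * row["n_unmasked_bins"] - row["sleep_minutes"]
                assert wake_minutes >= 0
                assert row["sleep_minutes"] + wake_minutes == 5 * row["n_unmasked_bins"]

    def test_group_sleep_matches_programmed_stationary(self, make_recording):
        # homogeneous chain: stationary sleep 0.4 -> 576 sleep min/day
        cfg = GenotypeSimConfig(
            label="g", n_flies=12, activity_template=np.full(288, 8.0),
            p_wake_to_sleep=0.2, p_sleep_to_wake=0.3, age_decline=1.0,
            lifespan_median_days=60.0,
        )
        recs, truth = simulate_cohort(cfg, seed=21, n_days=20)
        rows = []
        for rec in recs:
            slp, vit = self._score(rec)
            rows.append(daily_summaries(rec, slp, vit)["sleep_minutes"].mean())
        expected = truth.stationary_sleep * 1440
        assert np.mean(rows) == pytest.approx(expected, rel=0.02)
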
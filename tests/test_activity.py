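"""Tests for the locomotor-activity pipeline: parsing, filtering, profiles, tests."""

import numpy as np
import pandas as pd
import pytest

from midlink.activity import (
    ActivityTable,
    LightSchedule,
    daily_profile,
    filter_inactive,
    per_bin_comparison,
    per_fly_profiles,
    read_dam,
    rebin,
    transition_indices,
)
from midlink.synthetic import (
    ActivitySimConfig,
    morning_peak_bins,
    simulate_activity,
    write_dam,
    write_monitor,
)

SCHEDULE = LightSchedule(lights_on=8, lights_off=20)


def make_table(counts, bin_width=5, genotypes=None, start="2024-01-01"):
    arr = np.asarray(counts)
    flies = [f"g_fly{i:02d}" for i in range(arr.shape[1])]
    idx = pd.date_range(start, periods=arr.shape[0], freq=f"{bin_width}min")
    genos = pd.Series(genotypes or {f: "g" for f in flies})
    return ActivityTable(
        counts=pd.DataFrame(arr, index=idx, columns=flies),
        genotypes=genos,
        bin_width=bin_width,
        schedule=SCHEDULE,
    )


class TestReadDam:
    def test_long_format_roundtrip(self, tmp_path):
        table = simulate_activity(ActivitySimConfig(n_flies_per_genotype=2, n_days=1, seed=0), ["a"])
        p = tmp_path / "long.tsv"
        write_dam(table, p)
        back = read_dam(p, SCHEDULE)
        assert back.counts.sort_index(axis=1).equals(table.counts.sort_index(axis=1))

    def test_monitor_format_roundtrip(self, tmp_path):
        table = simulate_activity(ActivitySimConfig(n_flies_per_genotype=2, n_days=1, seed=1), ["a"])
        p = tmp_path / "Monitor1.txt"
        write_monitor(table, p)
        gmap = {f"Monitor1#{i:02d}": "a" for i in (1, 2)}
        back = read_dam(p, SCHEDULE, genotype_map=gmap)
        assert back.counts.shape == table.counts.shape
        assert np.array_equal(back.counts.to_numpy(), table.counts.to_numpy())

    def test_missing_interval_names_gap(self, tmp_path):
        table = simulate_activity(ActivitySimConfig(n_flies_per_genotype=1, n_days=1, seed=2), ["a"])
        df = table.counts.drop(table.counts.index[5])
        long = df.stack().rename("count").reset_index()
        long.columns = ["timestamp", "fly_id", "count"]
        p = tmp_path / "gap.tsv"
        long[["fly_id", "timestamp", "count"]].to_csv(p, sep="\t", index=False)
        with pytest.raises(ValueError, match="grid|gap"):
            read_dam(p, SCHEDULE)

    def test_negative_count_rejected(self, tmp_path):
        p = tmp_path / "neg.tsv"
        p.write_text(
            "fly_id\ttimestamp\tcount\n"
            "f1\t2024-01-01 00:00:00\t1\nf1\t2024-01-01 00:05:00\t-2\n"
        )
        with pytest.raises(ValueError, match="negative"):
            read_dam(p, SCHEDULE)

    def test_invalid_status_rejected(self, tmp_path):
        p = tmp_path / "Monitor2.txt"
        p.write_text(
            "1\t01 Jan 24\t00:00:00\t1\t0\t0\t0\t0\t0\t0\t3\t4\n"
            "2\t01 Jan 24\t00:05:00\t51\t0\t0\t0\t0\t0\t0\t3\t4\n"
        )
        with pytest.raises(ValueError, match="status"):
            read_dam(p, SCHEDULE)

    def test_non_monotone_timestamps_rejected(self, tmp_path):
        p = tmp_path / "Monitor3.txt"
        p.write_text(
            "1\t01 Jan 24\t00:05:00\t1\t0\t0\t0\t0\t0\t0\t3\n"
            "2\t01 Jan 24\t00:00:00\t1\t0\t0\t0\t0\t0\t0\t4\n"
        )
        with pytest.raises(ValueError, match="increasing"):
            read_dam(p, SCHEDULE)


class TestFilterInactive:
    def test_all_zero_day_removed_active_retained(self):
        cfg = ActivitySimConfig(n_flies_per_genotype=3, n_days=4, baseline_rate=2.0,
                                morning_peak_height=0, evening_peak_height=0, seed=3)
        table = simulate_activity(cfg, ["a"])
        counts = table.counts.copy()
        counts.iloc[2 * 288 : 3 * 288, 0] = 0  # fly 0: silent on day 3
        table = ActivityTable(counts, table.genotypes, table.bin_width, table.schedule)
        kept, removed = filter_inactive(table)
        assert removed == [table.counts.columns[0]]
        assert kept.counts.shape[1] == 2

    def test_one_count_per_day_is_retained(self):
        counts = np.zeros((2 * 288, 1), dtype=int)
        counts[100, 0] = 1
        counts[288 + 7, 0] = 1
        kept, removed = filter_inactive(make_table(counts))
        assert removed == []

    def test_rolling_window_is_stricter(self):
        # one count at the very start and very end of a 2-day recording:
        # every calendar day has a count, but a sliding 24 h window
        # between them is silent
        counts = np.zeros((2 * 288, 1), dtype=int)
        counts[0, 0] = 1
        counts[-1, 0] = 1
        _, removed_aligned = filter_inactive(make_table(counts))
        _, removed_rolling = filter_inactive(make_table(counts), rolling=True)
        assert removed_aligned == []
        assert removed_rolling == ["g_fly00"]

    def test_exactly_the_planted_flies_removed(self):
        rng = np.random.default_rng(4)
        cfg = ActivitySimConfig(n_flies_per_genotype=10, n_days=3, baseline_rate=3.0, seed=5)
        table = simulate_activity(cfg, ["a"])
        counts = table.counts.copy()
        planted = list(rng.choice(10, size=3, replace=False))
        for f in planted:
            day = int(rng.integers(3))
            counts.iloc[day * 288 : (day + 1) * 288, f] = 0
        table = ActivityTable(counts, table.genotypes, table.bin_width, table.schedule)
        _, removed = filter_inactive(table)
        assert sorted(removed) == sorted(table.counts.columns[i] for i in planted)


class TestRebin:
    def test_sums_within_groups(self):
        counts = np.array([[1], [0], [2], [0], [0], [1]])
        out = rebin(make_table(counts), 30)
        assert out.counts.iloc[0, 0] == 4
        assert out.n_bins == 1

    def test_totals_conserved_exactly(self):
        table = simulate_activity(ActivitySimConfig(n_flies_per_genotype=4, seed=6), ["a"])
        out = rebin(table, 30)
        assert np.array_equal(
            out.counts.sum().to_numpy(), table.counts.sum().to_numpy()
        )

    def test_same_width_is_identity(self):
        table = make_table(np.arange(12).reshape(-1, 1))
        assert rebin(table, 5) is table

    def test_non_divisible_width_rejected(self):
        with pytest.raises(ValueError, match="multiple"):
            rebin(make_table(np.zeros((12, 1))), 7)


class TestDailyProfile:
    def test_constant_counts_flat_profile(self):
        counts = np.full((7 * 48, 3), 2)
        table = make_table(counts, bin_width=30)
        prof = daily_profile(table)
        assert np.allclose(prof.mean["g"], 2.0)
        assert np.allclose(prof.sem["g"], 0.0)
        assert prof.n_flies["g"] == 3

    def test_single_day_profile_equals_that_day(self):
        rng = np.random.default_rng(7)
        counts = rng.integers(0, 5, size=(48, 2))
        prof = daily_profile(make_table(counts, bin_width=30))
        assert np.allclose(prof.mean["g"], counts.mean(axis=1))

    def test_profile_tracks_configured_rates(self):
        cfg = ActivitySimConfig(n_flies_per_genotype=100, seed=8)
        table = rebin(simulate_activity(cfg, ["a"]), 30)
        prof = daily_profile(table)
        from midlink.synthetic import activity_rate_curve

        rate30 = activity_rate_curve(cfg).reshape(48, 6).sum(axis=1)
        assert np.abs(prof.mean["a"] - rate30).sum() / rate30.sum() < 0.05

    def test_fold_respects_clock_time_when_start_is_not_midnight(self):
        counts = np.zeros((48, 1))
        counts[0] = 10  # first bin of a recording starting at 06:00
        prof = daily_profile(make_table(counts, bin_width=30, start="2024-01-01 06:00"))
        assert prof.mean["g"][12] == 10  # 06:00 = bin 13 (1-based)


class TestPerBinComparison:
    def test_knockdown_power_at_morning_bins(self):
        cfg = ActivitySimConfig(seed=9)  # 16 flies/genotype, multiplier 0.2
        table = rebin(simulate_activity(cfg, ["ctrl", "kd"], knockdown=["kd"]), 30)
        cmp_ = per_bin_comparison(per_fly_profiles(table))
        bins = morning_peak_bins(cfg)
        assert cmp_.flagged[bins].mean() >= 0.8

    def test_one_fly_per_genotype_rejected(self):
        with pytest.raises(ValueError, match="2 flies"):
            per_bin_comparison({"a": np.ones((1, 48)), "b": np.ones((1, 48))})

    def test_unbalanced_grid_rejected(self):
        with pytest.raises(ValueError, match="[Uu]nbalanced"):
            per_bin_comparison({"a": np.ones((3, 48)), "b": np.ones((4, 48))})

    def test_null_flag_rate_near_alpha(self):
        rng = np.random.default_rng(10)
        flags = []
        for _ in range(300):
            groups = {g: rng.normal(size=(8, 12)) for g in "ab"}
            flags.append(per_bin_comparison(groups).flagged)
        rate = np.mean(flags)
        assert 0.035 < rate < 0.065

    def test_bonferroni_is_stricter(self):
        rng = np.random.default_rng(11)
        groups = {"a": rng.normal(size=(8, 12)), "b": rng.normal(0.6, 1, size=(8, 12))}
        plain = per_bin_comparison(groups)
        bonf = per_bin_comparison(groups, bonferroni=True)
        assert bonf.flagged.sum() <= plain.flagged.sum()


class TestTransitionIndices:
    def test_flat_profile(self):
        out = transition_indices(np.ones(48), SCHEDULE)
        assert out.light_dark_ratio == pytest.approx(1.0)
        assert out.anticipation_on == pytest.approx(0.5)
        assert out.anticipation_off == pytest.approx(0.5)

    def test_all_activity_in_final_three_hours_before_lights_off(self):
        prof = np.zeros(48)
        # lights off at 20:00; bins 34..39 cover 17:00-20:00
        prof[34:40] = 5.0
        out = transition_indices(prof, SCHEDULE)
        assert out.anticipation_off == pytest.approx(1.0)

    def test_linear_ramp_gives_three_quarters(self):
        prof = np.zeros(48)
        # ramp rising linearly over the 6 h before lights-off (14:00-20:00)
        for i in range(28, 40):
            center_h = (i + 0.5) * 0.5
            prof[i] = center_h - 14.0
        out = transition_indices(prof, SCHEDULE)
        assert out.anticipation_off == pytest.approx(0.75)

    def test_zero_denominator_marked_undefined(self):
        prof = np.zeros(48)
        prof[0] = 1.0  # activity only at 00:00-00:30
        out = transition_indices(prof, SCHEDULE)
        assert out.anticipation_off is None

    def test_light_dark_ratio_inversion_detected(self):
        prof = np.ones(48)
        hours = (np.arange(48) + 0.5) * 0.5
        dark = ~np.array([SCHEDULE.is_light(h) for h in hours])
        prof[dark] = 3.0
        out = transition_indices(prof, SCHEDULE)
        assert out.light_dark_ratio == pytest.approx(1.0 / 3.0)
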
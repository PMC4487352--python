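import numpy as np
import pandas as pd
import pytest

from isocall import group_stats as gs
from isocall.features import CallFeatures


class TestAgeBin:
    @pytest.mark.parametrize("day,expected", [
        (30, 1.0), (35, 1.0),
        (36, 1.5), (42, 1.5),
        (44, 2.0), (58, 2.0),
        (64, 3.0), (103, 3.0),
        (29, None), (43, None), (59, None), (63, None), (104, None),
    ])
    def test_binning(self, day, expected):
        assert gs.age_bin(day) == expected

    def test_day_below_one_rejected(self):
        with pytest.raises(ValueError):
            gs.age_bin(0)


def _call(cls="voiced", f0=1000.0, dur=0.5, level=65.0, hr_sd=0.01):
    return CallFeatures(duration_s=dur, level_db=level, call_class=cls,
                        f0_mean_hz=f0, f0_max_hz=f0 + 100, f0_sd_hz=10.0,
                        t_f0max_s=0.05, hr_mean=2.0, hr_sd=hr_sd, hr_max=2.1,
                        t_hrmax_s=0.1, hr_at_f0max=2.0)


class TestSummarizeSession:
    META = {"session_id": "s1", "animal_id": "a1", "group": "hearing",
            "postnatal_day": 33}

    def test_single_call_equals_its_features(self):
        s = gs.summarize_session([_call()], self.META)
        assert s.f0_mean_hz == 1000.0
        assert s.duration_s == 0.5
        assert s.n_calls == 1
        assert s.pct_voiced == 100.0
        assert s.age_bin == 1.0

    def test_mean_of_two_calls(self):
        s = gs.summarize_session([_call(f0=900), _call(f0=1100)], self.META)
        assert s.f0_mean_hz == pytest.approx(1000.0)

    def test_pct_voiced(self):
        calls = [_call() for _ in range(8)] + \
                [_call(cls="unvoiced") for _ in range(2)]
        s = gs.summarize_session(calls, self.META)
        assert s.pct_voiced == pytest.approx(80.0)

    def test_hr_over_voiced_only(self):
        bad = _call(cls="unvoiced")
        bad.hr_mean = float("nan")
        s = gs.summarize_session([_call(), bad], self.META)
        assert s.hr_mean == pytest.approx(2.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gs.summarize_session([], self.META)

    def test_grand_mean_is_mean_of_session_means(self):
        """Pooling order: the grand mean averages session means, it is not
        call-weighted."""
        s1 = gs.summarize_session([_call(f0=900)] * 9, self.META)
        s2 = gs.summarize_session([_call(f0=1100)], self.META)
        df = gs.summaries_frame([s1, s2])
        gm = gs.grand_means(df)
        assert gm.loc["hearing", "f0_mean_hz"] == pytest.approx(1000.0)


class TestNormalityTest:
    def test_alpha_calibration_on_normal_samples(self):
        rng = np.random.default_rng(11)
        passed = sum(gs.normality_test(rng.normal(0, 1, 50))[1]
                     for _ in range(400))
        assert 0.86 <= passed / 400 <= 0.94

    def test_constant_sample_fails(self):
        stat, ok = gs.normality_test(np.full(20, 3.0))
        assert not ok

    def test_power_on_exponential(self):
        rng = np.random.default_rng(12)
        rejected = sum(not gs.normality_test(rng.exponential(1, 100))[1]
                       for _ in range(100))
        assert rejected >= 95

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            gs.normality_test(np.arange(4))


class TestCompareGroups:
    def test_identical_samples(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        var_r, mean_r = gs.compare_groups(a, a.copy())
        assert mean_r.statistic == pytest.approx(0.0, abs=1e-12)
        assert mean_r.p_value == pytest.approx(1.0)
        assert var_r.statistic == pytest.approx(1.0)

    def test_textbook_pooled_t(self):
        """a={1..5}, b={2..6}: means 3 and 4, both variances 2.5, pooled
        t = -1 / sqrt(2.5*(1/5+1/5)) = -1.0, df = 8, p = 0.3466 (hand
        computation from the standard two-sample formula)."""
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = np.array([2.0, 3.0, 4.0, 5.0, 6.0])
        var_r, mean_r = gs.compare_groups(a, b)
        assert mean_r.equal_var_assumed
        assert mean_r.statistic == pytest.approx(-1.0)
        assert mean_r.df == 8
        assert mean_r.p_value == pytest.approx(0.3466, abs=0.0005)

    def test_strong_shift_detected(self):
        rng = np.random.default_rng(13)
        detected = sum(
            gs.compare_groups(rng.normal(0, 1, 20),
                              rng.normal(3, 1, 20))[1].p_value < 0.001
            for _ in range(100))
        assert detected >= 99

    def test_unequal_variance_switches_to_welch(self):
        rng = np.random.default_rng(14)
        a = rng.normal(0, 1, 30)
        b = rng.normal(0, 10, 30)
        var_r, mean_r = gs.compare_groups(a, b)
        assert var_r.p_value < 0.05
        assert not mean_r.equal_var_assumed

    def test_zero_variance_both_rejected(self):
        with pytest.raises(ValueError):
            gs.compare_groups(np.ones(5), np.ones(5))

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(15)
        rejections = sum(
            gs.compare_groups(rng.normal(0, 1, 8),
                              rng.normal(0, 1, 8))[1].p_value < 0.05
            for _ in range(400))
        assert 0.02 <= rejections / 400 <= 0.08


class TestDevelopmentalTable:
    def _summaries(self, effect=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for group in ("hearing", "deaf"):
            for age, day in ((1.0, 32), (1.5, 39), (2.0, 50), (3.0, 80)):
                for i in range(4):
                    f0 = {1.0: 1100, 1.5: 1000, 2.0: 900, 3.0: 800}[age]
                    level = 65 + (effect if group == "deaf" else 0)
                    rows.append(dict(
                        session_id=f"{group}{age}{i}", animal_id="x",
                        group=group, postnatal_day=day, age_bin=age,
                        n_calls=40, pct_voiced=90.0,
                        duration_s=0.6 + rng.normal(0, 0.02),
                        level_db=level + rng.normal(0, 1),
                        f0_mean_hz=f0 + rng.normal(0, 20)))
        return pd.DataFrame(rows)

    def test_f0_decline_recovered_within_groups(self):
        df = self._summaries(seed=1)
        table = gs.developmental_table(df, features=("f0_mean_hz",))
        t = table[(table.test == "t_two_tailed") &
                  (table.group_a == table.group_b)]
        # every adjacent-age comparison has the younger mean higher
        adj = t[t.age_b - t.age_a <= 1.0]
        assert len(adj) > 0
        assert (adj.mean_a > adj.mean_b).all()

    def test_group_level_offset_detected_every_age(self):
        df = self._summaries(effect=10.0, seed=2)
        table = gs.developmental_table(df, features=("level_db",))
        t = table[(table.test == "t_two_tailed") &
                  (table.age_a == table.age_b)]
        assert len(t) == 4
        assert (t.p < 0.05).all()

    def test_identical_groups_alpha_level(self):
        """Fraction of significant comparisons between two identically
        distributed groups stays near alpha."""
        n_tests = 0
        n_sig = 0
        for seed in range(50):
            df = self._summaries(effect=0.0, seed=seed + 100)
            table = gs.developmental_table(df, features=("level_db",))
            t = table[(table.test == "t_two_tailed") &
                      (table.age_a == table.age_b)]
            n_tests += len(t)
            n_sig += int((t.p < 0.05).sum())
        assert n_sig / n_tests < 0.12

    def test_single_age_bin_rejected(self):
        df = self._summaries()
        with pytest.raises(ValueError):
            gs.developmental_table(df[df.age_bin == 1.0])
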
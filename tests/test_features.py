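"""Feature estimators against brute-force and closed-form oracles."""

import math

import numpy as np
import pytest

from relapsekit import features as F


def ls_direct(t, x, freqs, center=True):
    """Dense direct evaluation of the Lomb-Scargle definition (independent
    oracle: explicit tau then the two projected sums per frequency)."""
    x = np.asarray(x, float)
    if center:
        x = x - x.mean()
    out = []
    for f in freqs:
        w = 2 * np.pi * f
        tau = math.atan2(np.sum(np.sin(2 * w * t)),
                         np.sum(np.cos(2 * w * t))) / (2 * w)
        c = np.cos(w * (t - tau))
        s = np.sin(w * (t - tau))
        out.append(0.5 * ((x @ c) ** 2 / (c @ c) + (x @ s) ** 2 / (s @ s)))
    return np.array(out)


class TestShortTimeEnergy:
    def test_zero_window(self):
        assert F.short_time_energy(np.zeros((100, 3))) == 0.0

    def test_constant_unit_vector(self):
        w = np.tile([1.0, 0.0, 0.0], (50, 1))
        assert F.short_time_energy(w) == pytest.approx(1.0)

    def test_matches_loop_oracle(self, rng):
        w = rng.standard_normal((200, 3))
        expected = sum(w[i, 0] ** 2 + w[i, 1] ** 2 + w[i, 2] ** 2
                       for i in range(200)) / 200
        assert F.short_time_energy(w) == pytest.approx(expected, abs=1e-9)


class TestLombScargle:
    def test_zero_signal(self, rng):
        t = np.sort(rng.uniform(0, 100, 64))
        p = F.lomb_scargle(t, np.zeros(64), np.linspace(0.01, 0.4, 50))
        assert np.allclose(p.power, 0.0)

    def test_peak_at_cosine_frequency(self, rng):
        t = np.sort(rng.uniform(0, 300, 250))
        x = np.cos(2 * np.pi * 0.10 * t)
        grid = np.linspace(0.001, 0.5, 1024)
        p = F.lomb_scargle(t, x, grid)
        step = grid[1] - grid[0]
        assert abs(grid[np.argmax(p.power)] - 0.10) <= step + 1e-12

    def test_matches_direct_definition(self, rng):
        t = np.sort(rng.uniform(0, 200, 120))
        x = 800 + 30 * rng.standard_normal(120)
        grid = np.linspace(0.01, 0.45, 64)
        ours = F.lomb_scargle(t, x, grid).power
        oracle = ls_direct(t, x, grid)
        assert np.max(np.abs(ours - oracle) / np.maximum(oracle, 1e-12)) < 1e-6

    def test_uniform_sampling_matches_classical_periodogram(self):
        n = 256
        t = np.arange(n) / 5.0
        x = np.cos(2 * np.pi * 0.1 * t + 0.3)
        k = np.arange(1, n // 2)
        fk = k * 5.0 / n                       # Fourier frequencies
        ours = F.lomb_scargle(t, x, fk).power
        classical = np.abs(np.fft.rfft(x - x.mean())) ** 2 / n
        rel = np.abs(ours - classical[1 : n // 2]) / np.maximum(
            classical[1 : n // 2], 1e-12)
        assert rel.max() < 1e-6

    def test_no_center_leaks_dc(self, rng):
        t = np.sort(rng.uniform(0, 200, 100))
        x = np.full(100, 5.0) + 0.01 * rng.standard_normal(100)
        grid = np.linspace(0.01, 0.1, 16)
        raw = F.lomb_scargle(t, x, grid, center=False).power
        centered = F.lomb_scargle(t, x, grid, center=True).power
        assert raw.max() > 100 * centered.max()

    def test_requires_increasing_times(self):
        with pytest.raises(ValueError):
            F.lomb_scargle([0.0, 0.0, 1.0, 2.0], [1, 2, 3, 4])


class TestBandPowers:
    def _flat(self):
        return F.Periodogram(np.linspace(0.001, 0.5, 1024), np.ones(1024), 1024)

    def test_flat_spectrum_band_width_ratio(self):
        bp = F.band_powers(self._flat())
        assert bp.lf_pct == pytest.approx(100 * 0.11 / 0.36, abs=1e-6)

    def test_all_power_in_hf(self):
        freqs = np.linspace(0.001, 0.5, 1024)
        power = np.where((freqs > 0.2) & (freqs < 0.3), 1.0, 0.0)
        bp = F.band_powers(F.Periodogram(freqs, power, 1024))
        assert bp.lf_pct == pytest.approx(0.0)
        assert bp.hf_pct == pytest.approx(100.0)

    def test_percentages_sum_to_100(self, rng):
        freqs = np.linspace(0.001, 0.5, 512)
        for _ in range(20):
            bp = F.band_powers(F.Periodogram(freqs, rng.random(512), 512))
            assert bp.lf_pct + bp.hf_pct == pytest.approx(100.0, abs=1e-9)

    def test_zero_band_power_flagged(self):
        freqs = np.linspace(0.001, 0.5, 512)
        assert F.band_powers(F.Periodogram(freqs, np.zeros(512), 512)) is None


def sampen_brute(x, m, r):
    x = np.asarray(x, float)
    n = len(x)
    tol = r * x.std()

    def count(mm):
        c = 0
        for i in range(n - m):
            for j in range(n - m):
                if i == j:
                    continue
                if max(abs(x[i + k] - x[j + k]) for k in range(mm)) <= tol:
                    c += 1
        return c // 2

    b, a = count(m), count(m + 1)
    return float("nan") if (a == 0 or b == 0) else -math.log(a / b)


class TestSampleEntropy:
    def test_constant_sequence_is_zero(self):
        assert F.sample_entropy(np.full(50, 3.0)) == 0.0

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_pair_count(self, seed):
        x = np.random.default_rng(seed).standard_normal(30)
        ours = F.sample_entropy(x, 2, 0.5)
        oracle = sampen_brute(x, 2, 0.5)
        assert (math.isnan(ours) and math.isnan(oracle)) or ours == pytest.approx(
            oracle, abs=1e-12)

    def test_noise_exceeds_its_cumsum(self):
        wins = 0
        for seed in range(100):
            r = np.random.default_rng(seed).standard_normal(300)
            a = F.sample_entropy(r, 2, 0.2)
            b = F.sample_entropy(np.cumsum(r), 2, 0.2)
            if not (math.isnan(a) or math.isnan(b)) and a > b:
                wins += 1
        assert wins >= 95


class TestHiguchi:
    def test_straight_line(self):
        assert F.higuchi_fd(np.arange(200.0)) == pytest.approx(1.0, abs=0.02)

    def test_white_noise_near_two(self):
        vals = [F.higuchi_fd(np.random.default_rng(s).standard_normal(1000))
                for s in range(20)]
        assert abs(np.mean(vals) - 2.0) < 0.1

    def test_curve_lengths_match_per_offset_oracle(self, rng):
        x = rng.standard_normal(100)
        k_max = 6
        ours = F.higuchi_curve_lengths(x, k_max)
        n = len(x)
        for k in range(1, k_max + 1):
            lm = []
            for m0 in range(k):
                pts = x[m0::k]
                if len(pts) < 2:
                    continue
                norm = (n - 1) / ((len(pts) - 1) * k)
                lm.append(np.abs(np.diff(pts)).sum() * norm / k)
            assert ours[k - 1] == pytest.approx(np.mean(lm), abs=1e-12)


class TestMFD:
    def test_straight_line_dimension_one(self):
        prof = F.mfd_profile(0.5 * np.arange(1000.0))
        assert prof.dimensions == pytest.approx(np.ones_like(prof.dimensions),
                                                abs=1e-9)

    def test_bounds_on_any_signal(self, rng):
        for sig in (np.sin(2 * np.pi * np.arange(1000) / 70),
                    rng.standard_normal(1000),
                    np.cumsum(rng.standard_normal(1000))):
            d = F.mfd_profile(sig).dimensions
            assert (d >= 1.0).all() and (d <= 2.0).all()

    def test_cover_widths_match_neighborhood_oracle(self, rng):
        x = rng.standard_normal(200)
        widths = F.morphological_cover_widths(x, 5)
        for s in (1, 3, 5):
            for n in range(len(x)):
                lo, hi = max(0, n - s), min(len(x), n + s + 1)
                assert widths[s - 1, n] == pytest.approx(
                    x[lo:hi].max() - x[lo:hi].min(), abs=1e-12)

    def test_constant_signal_dimension_one(self):
        d = F.mfd_profile(np.full(200, 2.0)).dimensions
        assert np.allclose(d, 1.0)

    def test_summaries_consistent(self, rng):
        s = F.mfd_profile(rng.standard_normal(500)).summaries()
        assert s["mfd_min"] <= s["mfd_mean"] <= s["mfd_max"]
        assert s["mfd_min"] <= s["mfd_fd1"] <= s["mfd_max"]


class TestPoincare:
    def test_constant_series(self):
        assert F.poincare_sd(np.full(10, 800.0)) == (0.0, 0.0)

    def test_sd1_equals_rmssd_over_sqrt2(self, rng):
        rr = 800 + 40 * rng.standard_normal(500)
        sd1, _ = F.poincare_sd(rr)
        rmssd = np.sqrt(np.mean(np.diff(rr) ** 2))
        assert sd1 == pytest.approx(rmssd / math.sqrt(2), abs=1e-9)

    def test_variance_identity(self, rng):
        rr = 800 + 40 * rng.standard_normal(5000)
        sd1, sd2 = F.poincare_sd(rr)
        total = rr[1:].var() + rr[:-1].var()
        assert sd1**2 + sd2**2 == pytest.approx(total, rel=1e-2)
        assert sd1**2 + sd2**2 == pytest.approx(2 * rr.var(), rel=2e-2)


class TestTimeTrig:
    def test_midnight(self):
        assert F.time_of_day_trig(0.0) == pytest.approx((0.0, 1.0))

    def test_six_am(self):
        assert F.time_of_day_trig(6 * 3600.0) == pytest.approx((1.0, 0.0), abs=1e-12)


class TestDailyActivity:
    import pandas as pd

    def _diary(self):
        from relapsekit.synthetic import SleepDiary
        return SleepDiary(episodes=[(0.0, 8 * 3600.0)])

    def test_under_20_hours_excluded(self):
        import pandas as pd
        steps = pd.DataFrame({"day": [0], "steps": [100]})
        out = F.daily_activity(steps, self._diary(), {0: 19.9})
        assert len(out) == 0

    def test_ratio_eight_sixteen(self):
        import pandas as pd
        steps = pd.DataFrame({"day": [0], "steps": [100]})
        out = F.daily_activity(steps, self._diary(), {0: 24.0})
        assert out["sleep_wake_ratio"].iloc[0] == pytest.approx(0.5)

    def test_recovers_generator_sleep_fraction(self):
        import pandas as pd

        from relapsekit import synthetic as syn
        cfg = syn.CohortConfig(1, 0, 2, seed=23)
        prof = syn.make_profiles(cfg)[0]
        diary = syn.build_diary(prof, cfg)
        steps = pd.DataFrame({"day": [0, 1], "steps": [0, 0]})
        out = F.daily_activity(steps, diary, {0: 24.0, 1: 24.0})
        slept0 = sum(max(0.0, min(e, 86400.0) - max(s, 0.0))
                     for s, e in diary.episodes) / 3600.0
        expected = slept0 / (24.0 - slept0)
        assert out["sleep_wake_ratio"].iloc[0] == pytest.approx(expected, rel=1e-6)


class TestIntervalFeatures:
    def test_requires_a_modality(self):
        with pytest.raises(ValueError):
            F.interval_features(0.0)

    def test_midnight_window_trig(self, one_day_bundle):
        from relapsekit.preprocessing import clean_motion_window
        w = np.zeros((6000, 3))
        mw = clean_motion_window(w, 0.0, "acc")
        row = F.interval_features(0.0, acc_window=mw)
        assert row["sin_t"] == pytest.approx(0.0)
        assert row["cos_t"] == pytest.approx(1.0)

    def test_componentwise_against_per_feature_oracles(self, one_day_bundle):
        """Full synthetic window: every feature equals its independently
        scripted computation on the same cleaned data."""
        from relapsekit.preprocessing import clean_rr_window, dedupe_rr
        _, _, bundle = one_day_bundle
        rr_t, rr_v = dedupe_rr(bundle["rr"].times, bundle["rr"].values)
        w0 = 12 * 3600.0
        sel = slice(*np.searchsorted(rr_t, (w0, w0 + 300.0)))
        rrw = clean_rr_window(rr_t[sel], rr_v[sel], w0)
        row = F.interval_features(w0, rr_window=rrw, mode="full")

        rr = rrw.rr
        assert row["rr_mean"] == pytest.approx(rr.mean())
        assert row["hr_mean"] == pytest.approx(np.mean(60000.0 / rr))
        sd1, sd2 = F.poincare_sd(rr)
        assert row["sd1"] == pytest.approx(sd1)
        assert row["sd2"] == pytest.approx(sd2)
        assert row["sampen"] == pytest.approx(F.sample_entropy(rr, 2, 0.2))
        assert row["higuchi"] == pytest.approx(F.higuchi_fd(rr, 10))
        grid = np.linspace(0.001, 0.5, 1024)
        oracle_band = F.band_powers(
            F.Periodogram(grid, ls_direct(rrw.beat_times, rr, grid), len(rr)))
        assert row["lf_pct"] == pytest.approx(oracle_band.lf_pct, abs=1e-6)
        assert row["lf_pct"] + row["hf_pct"] == pytest.approx(100.0)

    def test_pure_function(self, one_day_bundle):
        from relapsekit.preprocessing import clean_rr_window, dedupe_rr
        _, _, bundle = one_day_bundle
        rr_t, rr_v = dedupe_rr(bundle["rr"].times, bundle["rr"].values)
        w0 = 10 * 3600.0
        sel = slice(*np.searchsorted(rr_t, (w0, w0 + 300.0)))
        rrw = clean_rr_window(rr_t[sel], rr_v[sel], w0)
        a = F.interval_features(w0, rr_window=rrw, mode="full")
        b = F.interval_features(w0, rr_window=rrw, mode="full")
        assert a.keys() == b.keys()
        for key in a:
            x, y = a[key], b[key]
            if isinstance(x, float) and math.isnan(x):
                assert math.isnan(y)
            else:
                assert x == y
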
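"""Generator contracts: validation, determinism, artifact rates, labels,
effect-size realization and session synthesis."""

import numpy as np
import pytest
from scipy import stats

from relapsekit import synthetic as syn
from relapsekit.preprocessing import dedupe_rr


class TestConfigValidation:
    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            syn.ArtifactRates(rr_outlier_rate=-0.1)

    def test_zero_days_rejected(self):
        with pytest.raises(ValueError):
            syn.CohortConfig(1, 1, 0)

    def test_relapse_window_must_fit_period(self):
        with pytest.raises(ValueError):
            syn.CohortConfig(0, 1, 5, relapses=[syn.RelapseSpec(0, 4, 3)])

    def test_unknown_effect_handle_rejected(self):
        with pytest.raises(ValueError):
            syn.CohortConfig(1, 1, 1, effect_sizes={"nope": 1.0})

    def test_severity_mid_alias_and_bad_level(self):
        assert syn.RelapseSpec(0, 0, 1, "mid").severity == "moderate"
        with pytest.raises(ValueError):
            syn.RelapseSpec(0, 0, 1, "catastrophic")


class TestDeterminism:
    def test_same_seed_identical_streams(self):
        cfg = syn.CohortConfig(1, 0, 1, seed=11)
        prof = syn.make_profiles(cfg)[0]
        a = syn.simulate_subject_day(prof, cfg, 0)
        b = syn.simulate_subject_day(prof, cfg, 0)
        for mod in ("acc", "gyr", "rr", "steps"):
            assert np.array_equal(a[mod].times, b[mod].times)
            assert np.array_equal(a[mod].values, b[mod].values)

    def test_different_days_differ(self):
        cfg = syn.CohortConfig(1, 0, 2, seed=11)
        prof = syn.make_profiles(cfg)[0]
        a = syn.simulate_subject_day(prof, cfg, 0)
        b = syn.simulate_subject_day(prof, cfg, 1)
        assert not np.array_equal(a["rr"].values, b["rr"].values)


class TestStreams:
    def test_readout_dedupe_recovers_beat_count(self, one_day_bundle):
        _, _, bundle = one_day_bundle
        beat_t, _ = bundle["beats"]
        _, rr = dedupe_rr(bundle["rr"].times, bundle["rr"].values)
        # readout starts at the first beat, so every beat appears once
        assert abs(len(rr) - len(beat_t)) <= 1

    def test_nominal_rates_and_units(self, one_day_bundle):
        _, _, bundle = one_day_bundle
        assert bundle["acc"].nominal_rate == 20.0
        assert bundle["rr"].nominal_rate == 5.0
        assert bundle["acc"].values.shape[1] == 3
        assert 300 < np.median(bundle["rr"].values) < 2000

    def test_rr_outlier_rate_matches_binomial(self):
        rate = 0.01
        cfg = syn.CohortConfig(1, 0, 1, seed=3,
                               artifact_rates=syn.ArtifactRates(rate, 0.0, 0.0))
        prof = syn.make_profiles(cfg)[0]
        bundle = syn.simulate_subject_day(prof, cfg, 0)
        _, rr = bundle["beats"]
        frac = np.mean((rr < 300) | (rr > 2000))
        n = len(rr)
        ci = 4 * np.sqrt(rate * (1 - rate) / n)
        assert abs(frac - rate) < ci

    def test_gap_rate_removes_samples(self):
        cfg = syn.CohortConfig(1, 0, 1, seed=3,
                               artifact_rates=syn.ArtifactRates(0.0, 0.05, 0.0))
        prof = syn.make_profiles(cfg)[0]
        bundle = syn.simulate_subject_day(prof, cfg, 0)
        missing = 1 - len(bundle["acc"].times) / (86400 * 20)
        assert 0.005 < missing < 0.15


class TestCohort:
    def test_manifest_arithmetic(self, small_cohort_config):
        cohort = syn.simulate_cohort(
            syn.CohortConfig(2, 2, 3, seed=1))
        assert len(cohort.subjects) == 4
        assert cohort.manifest["n_subject_days"] == 12

    def test_groups_exchangeable_without_effects(self):
        profs = syn.make_profiles(syn.CohortConfig(3, 3, 1, seed=5))
        # no configured effects: latent distributions identical across groups
        assert {p.group for p in profs} == {"control", "patient"}


class TestLabels:
    def test_day_condition_windows_exact(self):
        ann = [syn.RelapseAnnotation("P", 10 * 86400.0, 12 * 86400.0,
                                     "severe", False, 1.0)]
        assert syn.day_condition(ann, 10, 3)[0] == "relapse"
        assert syn.day_condition(ann, 11, 3)[0] == "relapse"
        assert syn.day_condition(ann, 12, 3)[0] == "normal"   # half-open end
        assert syn.day_condition(ann, 9, 3)[0] == "near_relapse"
        assert syn.day_condition(ann, 7, 3)[0] == "near_relapse"
        assert syn.day_condition(ann, 6, 3)[0] == "normal"

    def test_prodrome_ramp_monotone_and_milder(self):
        ann = [syn.RelapseAnnotation("P", 10 * 86400.0, 12 * 86400.0,
                                     "moderate", False, 2.0)]
        m = [syn.day_condition(ann, d, 5)[1] for d in range(5, 10)]
        assert all(np.diff(m) >= 0)
        assert max(m) <= syn.PRODROME_PEAK_FRACTION * 2.0 + 1e-12
        assert syn.day_condition(ann, 10, 5)[1] == pytest.approx(2.0)

    def test_severity_multipliers_ordered(self):
        mags = [syn.SEVERITY_MULTIPLIER[s] for s in ("low", "moderate", "severe")]
        assert mags == sorted(mags) and len(set(mags)) == 3


class TestNullEffect:
    def test_zero_magnitude_relapse_indistinguishable(self):
        cfg = syn.CohortConfig(0, 1, 1, seed=9)
        prof = syn.make_profiles(cfg)[0]
        rng = np.random.default_rng(2)
        ste_a, ste_b, rr_a, rr_b = [], [], [], []
        for _ in range(100):
            iv = syn.simulate_interval(prof, cfg, "awake", 0.0, rng)
            ste_a.append(float((np.asarray(iv["acc"], float) ** 2).sum(1).mean()))
            rr_a.append(float(iv["beats"][1].mean()))
            iv = syn.simulate_interval(prof, cfg, "awake", 0.0, rng)
            ste_b.append(float((np.asarray(iv["acc"], float) ** 2).sum(1).mean()))
            rr_b.append(float(iv["beats"][1].mean()))
        assert stats.mannwhitneyu(ste_a, ste_b).pvalue > 0.01
        assert stats.mannwhitneyu(rr_a, rr_b).pvalue > 0.01


class TestEffectFidelity:
    def test_realized_shift_tracks_configured(self):
        """Configured standardized shifts are realized within +/-0.25 at
        n=50/50 subjects (calibrated handles, non-interacting pairs)."""
        import pandas as pd

        from relapsekit.group_stats import aggregate_subject
        from relapsekit.pipeline import trait_interval_table

        def realized(effects, feats):
            cfg = syn.CohortConfig(50, 50, 1, seed=0, effect_sizes=effects)
            tab = trait_interval_table(cfg, n_awake=64, n_sleep=8)
            parts = [aggregate_subject(sub, sid, grp, features=feats)
                     for (sid, grp), sub in tab.groupby(["subject_id", "group"])]
            aw = pd.concat(parts)
            aw = aw[aw.state == "awake"]

            def d(col):
                c = aw[aw.group == "control"][col]
                p = aw[aw.group == "patient"][col]
                return (p.mean() - c.mean()) / np.sqrt((c.var() + p.var()) / 2)

            return d

        d1 = realized({"ste_acc_mean": 1.0, "sd1_mean": 1.0}, ["ste_acc", "sd1"])
        assert abs(d1("ste_acc_mean") - 1.0) < 0.25
        assert abs(d1("sd1_mean") - 1.0) < 0.25
        d2 = realized({"ste_acc_std": 1.0, "rr_mean": -1.0}, ["ste_acc", "rr_mean"])
        assert abs(d2("ste_acc_std") - 1.0) < 0.25
        assert abs(d2("rr_mean_mean") + 1.0) < 0.25


class TestSessions:
    ANN = [syn.RelapseAnnotation("P0", 40 * 86400.0, 44 * 86400.0,
                                 "moderate", False, 1.0)]

    def test_slice_shape_and_nonnegativity(self):
        sessions = syn.simulate_sessions("P0", self.ANN, 5, 1.0, seed=1)
        for s in sessions:
            assert s.slices.shape[1:] == (128, 64)
            assert (s.slices >= 0).all()

    def test_thirty_day_rule(self):
        sessions = syn.simulate_sessions("P0", self.ANN, 40, 1.0, seed=2,
                                         period_days=80.0)
        for s in sessions:
            if 40 <= s.session_date < 44:
                assert s.state == "relapse"
            elif 10 <= s.session_date < 40:
                assert s.state == "pre_relapse"
            elif s.session_date < 10 or s.session_date >= 44:
                assert s.state == "clean"

    def test_all_clean_when_far_from_relapse(self):
        sessions = syn.simulate_sessions("P0", [], 10, 1.0, seed=3)
        assert all(s.state == "clean" for s in sessions)

    def test_mean_slice_count(self):
        sessions = syn.simulate_sessions("P0", [], 100, 0.0, seed=4,
                                         mean_slices=30.0)
        counts = [len(s.slices) for s in sessions]
        assert abs(np.mean(counts) - 30.0) < 3 * np.sqrt(30 / 100)

    def test_zero_magnitude_sessions_unscorable(self):
        aucs = []
        for seed in range(10):
            sessions = syn.simulate_sessions("P0", self.ANN, 30, 0.0, seed=seed,
                                             period_days=80.0, mean_slices=5.0)
            labels = [0 if s.state == "clean" else 1 for s in sessions]
            scores = [float(s.slices.mean()) for s in sessions]
            if len(set(labels)) < 2:
                continue
            from sklearn.metrics import roc_auc_score
            aucs.append(roc_auc_score(labels, scores))
        assert abs(np.mean(aucs) - 0.5) < 0.1

    def test_determinism(self):
        a = syn.simulate_sessions("P0", self.ANN, 4, 1.0, seed=5)
        b = syn.simulate_sessions("P0", self.ANN, 4, 1.0, seed=5)
        for x, y in zip(a, b):
            assert np.array_equal(x.slices, y.slices)
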
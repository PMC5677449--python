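"""Cohort simulator: design fidelity, determinism, controllability."""

import numpy as np
import pytest

from spiraltis import (
    HEALTHY_SCHEDULE,
    PATIENT_SCHEDULE,
    LevodopaResponse,
    SimulationConfig,
    apen,
    drawing_speed,
    downsample_every_second,
    render_trial,
    severity_time_course,
    simulate_cohort,
    weak_correlation_config,
    write_cohort,
)
from spiraltis.simulate import (
    DROPOUT_COUNTS,
    ratings_from_severity,
    simulate_trial_triples,
)


class TestDesignFidelity:
    def test_schedules_exact(self, tiny_cohort):
        for rec in tiny_cohort:
            minutes = tuple(o.minutes_from_dose for o in rec.occasions)
            expected = HEALTHY_SCHEDULE if rec.group == "healthy" else PATIENT_SCHEDULE
            assert minutes == tuple(float(m) for m in expected)

    def test_three_trials_per_occasion(self, tiny_cohort):
        for rec in tiny_cohort:
            for occ in rec.occasions:
                assert len(occ.trials) == 3
                assert [t.trial_index for t in occ.trials] == [1, 2, 3]

    def test_patients_have_ratings_healthy_do_not(self, tiny_cohort):
        for rec in tiny_cohort:
            for occ in rec.occasions:
                if rec.group == "healthy":
                    assert occ.ratings is None
                else:
                    assert occ.ratings is not None
                    assert set(occ.ratings) == {
                        "updrs23", "updrs25", "updrs26", "updrs27",
                        "updrs29", "updrs31", "dys",
                    }
                    assert all(0.0 <= v <= 4.0 for v in occ.ratings.values())

    def test_group_counts(self, tiny_cohort):
        groups = [r.group for r in tiny_cohort]
        assert groups.count("healthy") == 2
        assert groups.count("early") == 1
        assert groups.count("intermediate") == 1
        assert groups.count("advanced") == 1

    def test_empty_config_empty_cohort(self):
        cfg = SimulationConfig(
            n_healthy=0, n_early=0, n_intermediate=0, n_advanced=0
        )
        assert simulate_cohort(cfg) == []

    def test_dropout_reproduces_attrition_counts(self):
        cfg = SimulationConfig(
            seed=9, dropout=True, trial_duration_s=2.0, sample_interval_ms=40.0
        )
        records = [r for r in simulate_cohort(cfg) if r.group != "healthy"]
        assert len(records) == 19
        for minutes, expected in DROPOUT_COUNTS.items():
            observed = sum(
                any(o.minutes_from_dose == minutes for o in rec.occasions)
                for rec in records
            )
            assert observed == expected, f"at {minutes} min"
        # attrition is monotone: each patient keeps a prefix of the schedule
        for rec in records:
            minutes = [o.minutes_from_dose for o in rec.occasions]
            assert minutes == [
                m for m in PATIENT_SCHEDULE if m <= max(minutes)
            ]

    def test_determinism_byte_identical_files(self, tmp_path):
        cfg = SimulationConfig(
            n_healthy=1, n_early=1, n_intermediate=0, n_advanced=0,
            seed=123, trial_duration_s=2.0, sample_interval_ms=40.0,
        )
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_cohort(simulate_cohort(cfg), str(p1))
        write_cohort(simulate_cohort(cfg), str(p2))
        assert p1.read_bytes() == p2.read_bytes()


class TestSeverityTimeCourse:
    def test_zero_peak_effect_constant(self):
        resp = LevodopaResponse(peak_effect=0.0)
        traj = severity_time_course(2.0, resp, PATIENT_SCHEDULE)
        np.testing.assert_array_equal(traj, np.full(len(PATIENT_SCHEDULE), 2.0))

    def test_unimodal_shape_around_peak(self):
        resp = LevodopaResponse()
        assert resp.effect(45) > resp.effect(15)
        assert resp.effect(300) < resp.effect(120)
        assert resp.effect(-20) == 0.0
        assert resp.effect(resp.onset_delay_min) == 0.0

    def test_severity_never_negative(self):
        resp = LevodopaResponse(peak_effect=5.0)
        traj = severity_time_course(1.0, resp, PATIENT_SCHEDULE)
        assert np.all(traj >= 0.0)

    def test_healthy_trajectory_constant(self):
        traj = severity_time_course(
            0.3, LevodopaResponse(), HEALTHY_SCHEDULE, is_patient=False
        )
        np.testing.assert_array_equal(traj, np.full(len(HEALTHY_SCHEDULE), 0.3))


class TestRenderTrial:
    def test_zero_severity_regular_limit(self):
        cfg = SimulationConfig(sample_jitter_ms=0.0, drift_amplitude=0.0)
        trial = render_trial(0.0, cfg, np.random.default_rng(0))
        speed = drawing_speed(downsample_every_second(trial), validate=False)
        assert apen(speed) < 0.05

    def test_samples_within_screen_bounds(self):
        cfg = SimulationConfig()
        for seed in range(5):
            trial = render_trial(3.0, cfg, np.random.default_rng(seed))
            assert np.all((trial.x >= 0) & (trial.x <= cfg.device.width_px))
            assert np.all((trial.y >= 0) & (trial.y <= cfg.device.height_px))

    def test_higher_severity_more_irregular_paired_seeds(self):
        cfg = SimulationConfig()
        wins = 0
        n_pairs = 50
        for seed in range(n_pairs):
            low = render_trial(0.0, cfg, np.random.default_rng(seed))
            high = render_trial(3.0, cfg, np.random.default_rng(seed))
            a_low = apen(drawing_speed(downsample_every_second(low), validate=False))
            a_high = apen(drawing_speed(downsample_every_second(high), validate=False))
            wins += a_high > a_low
        assert wins >= 0.9 * n_pairs

    def test_completion_time_grows_with_severity(self):
        cfg = SimulationConfig(trial_duration_jitter=0.0)
        slow = render_trial(3.0, cfg, np.random.default_rng(1))
        fast = render_trial(0.0, cfg, np.random.default_rng(1))
        assert slow.duration_s > fast.duration_s

    def test_duration_near_nominal(self):
        cfg = SimulationConfig(trial_duration_jitter=0.0, completion_time_gain=0.0)
        trial = render_trial(1.0, cfg, np.random.default_rng(2))
        assert trial.duration_s == pytest.approx(10.0, rel=0.05)


class TestRatings:
    def run_ratings(self, severity, noise, seed=0, base=3.0):
        cfg = SimulationConfig(rater_noise_sd=noise)
        times = np.array(PATIENT_SCHEDULE, dtype=float)
        eff = cfg.pd_response.effect(times)
        eff_lag = cfg.pd_response.effect(times - cfg.dys_lag_min)
        sev = np.full(times.shape, severity)
        return times, eff, ratings_from_severity(
            sev, eff, eff_lag, cfg, np.random.default_rng(seed),
            baseline_severity=base,
        )

    def test_zero_noise_floor_severity_rates_zero(self):
        _, _, ratings = self.run_ratings(severity=0.1, noise=0.0, base=0.1)
        for occ in ratings:
            for item in ("updrs23", "updrs25", "updrs26", "updrs27", "updrs29", "updrs31"):
                assert occ[item] == 0.0

    def test_zero_noise_mean_equals_map_value(self):
        cfg = SimulationConfig(rater_noise_sd=0.0)
        _, _, ratings = self.run_ratings(severity=2.0, noise=0.0)
        expected = np.clip(1.0 * cfg.rating_slope * (2.0 - cfg.rating_floor), 0, 4)
        assert ratings[0]["updrs23"] == pytest.approx(expected)

    def test_severity_rating_correlation_strong(self):
        cfg = SimulationConfig(seed=21, rater_noise_sd=0.3,
                               trial_duration_s=2.0, sample_interval_ms=40.0)
        records = simulate_cohort(cfg)
        sev_proxy, item = [], []
        for rec in records:
            if rec.group == "healthy":
                continue
            base = cfg.severity_scale[rec.group]
            resp = cfg.pd_response
            for occ in rec.occasions:
                sev_proxy.append(
                    max(0.0, base - float(resp.effect(occ.minutes_from_dose)))
                )
                item.append(occ.ratings["updrs23"])
        r = np.corrcoef(sev_proxy, item)[0, 1]
        assert r > 0.8

    def test_dyskinesia_peaks_with_effect_not_severity(self):
        times, eff, ratings = self.run_ratings(severity=3.0, noise=0.0, base=3.0)
        dys = np.array([r["dys"] for r in ratings])
        assert dys[0] == 0.0  # baseline, pre-dose
        peak_idx = int(np.argmax(dys))
        lagged_peak = int(np.argmax(
            LevodopaResponse().effect(times - SimulationConfig().dys_lag_min)
        ))
        assert peak_idx == lagged_peak


class TestScoreLevelGenerators:
    def test_trial_triples_shape_and_icc_recovery(self):
        df = simulate_trial_triples(500, 0.8, seed=1)
        assert len(df) == 1500
        wide = df.pivot(index="occasion", columns="trial", values="score")
        between = wide.mean(axis=1).var(ddof=1)
        within = wide.var(axis=1, ddof=1).mean()
        icc_moments = (between - within / 3) / (between - within / 3 + within)
        assert icc_moments == pytest.approx(0.8, abs=0.08)

    def test_invalid_icc_rejected(self):
        with pytest.raises(ValueError):
            simulate_trial_triples(10, 1.5, seed=0)


class TestDirectionalControllability:
    def test_tis_increases_with_group_severity_without_time_coupling(self):
        from spiraltis import score_cohort

        cfg = SimulationConfig(
            n_healthy=3, n_early=3, n_intermediate=3, n_advanced=3,
            seed=31, completion_time_gain=0.0,
            trial_duration_s=5.0,
        )
        scored = score_cohort(simulate_cohort(cfg))
        means = scored.groupby("group")["occasion_tis"].mean()
        assert means["healthy"] < means["early"] < means["intermediate"] < means["advanced"]

    def test_tis_decreases_with_severity_under_strong_time_coupling(self):
        from spiraltis import score_cohort
        from dataclasses import replace

        cfg = replace(
            weak_correlation_config(seed=31),
            n_healthy=4, n_early=0, n_intermediate=0, n_advanced=4,
            trial_duration_s=5.0,
        )
        scored = score_cohort(simulate_cohort(cfg))
        means = scored.groupby("group")["occasion_tis"].mean()
        assert means["advanced"] < means["healthy"]
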
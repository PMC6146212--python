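"""Step segmentation, normalization, responses, outcomes, onsets."""

import numpy as np
import pytest
from scipy.stats import t as t_dist

from balancegait.events import GaitEvent
from balancegait.steps import (
    StepRecord,
    baseline_subtract,
    classify_and_mirror,
    compute_outcomes,
    estimate_onset,
    fit_foot_placement_model,
    mirror_record,
    normalize_time,
    pointwise_ci,
    segment_and_select,
    stimulus_induced_fp_change,
)
from balancegait.stimulus import StimulusEvent


def make_record(traj, *, step_index=1, condition="toward", direction="toward",
                stance="right", duration=0.667, po_frac=0.2, is_response=True):
    return StepRecord(
        subject="S01",
        stance_foot=stance,
        swing_foot="left" if stance == "right" else "right",
        t_start=0.0,
        t_end=duration,
        duration=duration,
        traj={k: np.asarray(v, dtype=float) for k, v in traj.items()},
        pushoff_frac=po_frac,
        step_index=step_index,
        condition=condition,
        trigger_foot=stance,
        direction=direction,
        is_response=is_response,
    )


class TestNormalizeTime:
    def test_linear_ramp_preserves_endpoints(self):
        t = np.linspace(0, 1, 173)
        y = normalize_time(t, t)
        assert len(y) == 100
        assert y[0] == 0.0 and y[-1] == 1.0
        assert np.max(np.abs(np.diff(y) - 1 / 99)) < 1e-12

    def test_constant_stays_constant(self):
        t = np.linspace(0, 0.6, 50)
        assert normalize_time(t, np.full(50, 4.2)) == pytest.approx(np.full(100, 4.2))

    def test_sinusoid_matches_analytic_resampling(self):
        t = np.linspace(0, 0.66, 166)
        y = normalize_time(t, np.sin(2 * np.pi * 3 * t))
        grid = np.linspace(0, 0.66, 100)
        assert y == pytest.approx(np.sin(2 * np.pi * 3 * grid), abs=5e-3)

    def test_degenerate_step_rejected(self):
        t = np.linspace(0, 0.02, 10)
        with pytest.raises(ValueError, match="degenerate"):
            normalize_time(t, t)


class TestSegmentAndSelect:
    def _events(self, n=20, period=0.6):
        hs = [
            GaitEvent(1.0 + k * period, "left" if k % 2 == 0 else "right", "heelstrike")
            for k in range(n)
        ]
        po = [GaitEvent(1.0 + k * period + 0.12, e.foot, "pushoff") for k, e in enumerate(hs[1:])]
        return hs, po

    def _channels(self, duration=14.0, nan_window=None):
        t = np.arange(0, duration, 1 / 250)
        y = np.sin(2 * np.pi * t / 1.2)
        if nan_window:
            y = y.copy()
            y[(t >= nan_window[0]) & (t <= nan_window[1])] = np.nan
        return {"com_pos": (t, y)}

    def test_one_stimulus_yields_exactly_six_steps(self):
        hs, po = self._events()
        stim = [StimulusEvent(1.0 + 8 * 0.6, "left", "right")]
        records = segment_and_select(hs, po, stim, self._channels())
        assert len(records) == 6
        assert sorted(r.step_index for r in records) == [-2, -1, 1, 2, 3, 4]
        assert sum(r.condition == "control" for r in records) == 2
        # step +1 starts at the triggering heelstrike
        plus1 = next(r for r in records if r.step_index == 1)
        assert plus1.t_start == pytest.approx(stim[0].trigger_time)
        assert plus1.stance_foot == "left"

    def test_gap_inside_step_plus2_excludes_only_it(self):
        hs, po = self._events()
        trigger = 1.0 + 8 * 0.6
        stim = [StimulusEvent(trigger, "left", "right")]
        # occlusion inside step +2 (trigger+period .. trigger+2*period)
        records = segment_and_select(
            hs, po, stim, self._channels(nan_window=(trigger + 0.7, trigger + 0.9))
        )
        by_index = {r.step_index: r for r in records}
        assert by_index[2].excluded
        assert not any(by_index[k].excluded for k in (-2, -1, 1, 3, 4))

    def test_no_stimuli_leaves_steps_unindexed(self):
        hs, po = self._events()
        records = segment_and_select(hs, po, [], self._channels())
        assert len(records) == len(hs) - 1
        assert all(r.step_index is None for r in records)


class TestClassifyAndMirror:
    def _record(self):
        return make_record(
            {"com_pos": np.ones(100), "stance_ankle_eversion": np.full(100, 2.0)},
            condition="stimulus",
            direction=None,
        )

    def test_direction_classification(self):
        toward = classify_and_mirror(self._record(), StimulusEvent(0.0, "right", "right"))
        assert toward.direction == "toward"
        away = classify_and_mirror(self._record(), StimulusEvent(0.0, "left", "right"))
        assert away.direction == "away"

    def test_left_trigger_mirrors_spatial_channels_only(self):
        rec = classify_and_mirror(self._record(), StimulusEvent(0.0, "left", "left"))
        assert rec.mirrored
        assert rec.traj["com_pos"] == pytest.approx(-np.ones(100))
        assert rec.traj["stance_ankle_eversion"] == pytest.approx(np.full(100, 2.0))

    def test_mirror_is_an_involution(self):
        rec = self._record()
        back = mirror_record(mirror_record(rec))
        assert not back.mirrored
        for k in rec.traj:
            assert back.traj[k] == pytest.approx(rec.traj[k])


class TestBaselineSubtract:
    def _control(self, value, stance="right"):
        return make_record(
            {"com_pos": np.full(100, value)},
            step_index=-1,
            condition="control",
            direction=None,
            stance=stance,
            is_response=False,
        )

    def test_step_equal_to_control_mean_gives_zero_response(self):
        controls = [self._control(1.0), self._control(3.0)]
        stim = make_record({"com_pos": np.full(100, 2.0)}, is_response=False)
        (resp,) = baseline_subtract([stim], controls)
        assert resp.is_response
        assert resp.traj["com_pos"] == pytest.approx(np.zeros(100))

    def test_controls_against_own_mean_have_zero_mean_residual(self):
        controls = [self._control(v) for v in (0.0, 1.0, 5.0)]
        responses = baseline_subtract(controls, controls)
        stacked = np.array([r.traj["com_pos"] for r in responses])
        assert stacked.mean(axis=0) == pytest.approx(np.zeros(100), abs=1e-12)

    def test_missing_control_side_raises(self):
        controls = [self._control(1.0, stance="right")]
        stim = make_record({"com_pos": np.zeros(100)}, stance="left", is_response=False)
        with pytest.raises(ValueError, match="left"):
            baseline_subtract([stim], controls)


class TestFootPlacementModel:
    def _control_records(self, a, b, n=30, noise=0.0, rng=None):
        rng = rng or np.random.default_rng(0)
        records = []
        for _ in range(n):
            p, v = rng.normal(0, 3), rng.normal(0, 10)
            y = a * p + b * v + (rng.normal(0, noise) if noise else 0.0)
            records.append(
                make_record(
                    {
                        "com_pos": np.full(100, p),
                        "com_vel": np.full(100, v),
                        "rel_heel_x": np.full(100, y),
                    },
                    step_index=-1,
                    condition="control",
                    direction=None,
                )
            )
        return records

    def test_noiseless_coefficients_recovered_to_machine_precision(self):
        model = fit_foot_placement_model(self._control_records(1.3, 0.22))
        assert model.coef_pos == pytest.approx(1.3, abs=1e-10)
        assert model.coef_vel == pytest.approx(0.22, abs=1e-10)
        assert model.intercept == pytest.approx(0.0, abs=1e-10)

    def test_injected_offset_recovered_exactly(self):
        model = fit_foot_placement_model(self._control_records(1.3, 0.22))
        step = make_record(
            {
                "com_pos": np.full(100, 2.0),
                "com_vel": np.full(100, -4.0),
                "rel_heel_x": np.full(100, 1.3 * 2.0 + 0.22 * -4.0 + 5.0),
            }
        )
        assert stimulus_induced_fp_change(step, model) == pytest.approx(5.0, abs=1e-10)

    def test_control_residuals_average_zero(self):
        records = self._control_records(1.0, 0.1, noise=2.0)
        model = fit_foot_placement_model(records)
        resid = [stimulus_induced_fp_change(r, model) for r in records]
        assert np.mean(resid) == pytest.approx(0.0, abs=1e-9)

    def test_rank_deficient_design_rejected(self):
        records = []
        for _ in range(12):
            records.append(
                make_record(
                    {
                        "com_pos": np.zeros(100),
                        "com_vel": np.zeros(100),
                        "rel_heel_x": np.zeros(100),
                    },
                    step_index=-1,
                    condition="control",
                    direction=None,
                )
            )
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_foot_placement_model(records)

    def test_too_few_control_steps_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            fit_foot_placement_model(self._control_records(1.0, 0.1, n=5))


class TestOutcomes:
    def test_constant_cop_shift_integrates_to_shift_times_window(self):
        s, T = 4.0, 0.8
        step = make_record({"cop_rel": np.full(100, s)}, duration=T, po_frac=0.0)
        row = compute_outcomes(step, None)
        assert row.integrated_relative_cop_change == pytest.approx(s * T, rel=1e-9)

    def test_window_starts_at_swing_pushoff(self):
        s, T, frac = 4.0, 0.8, 0.25
        step = make_record({"cop_rel": np.full(100, s)}, duration=T, po_frac=frac)
        row = compute_outcomes(step, None)
        expected = s * T * (1 - np.ceil(frac * 99) / 99)
        assert row.integrated_relative_cop_change == pytest.approx(expected, rel=1e-9)

    def test_sign_adjustment_by_direction(self):
        traj = {
            "rel_heel_x": np.full(100, 3.0),
            "stance_ankle_eversion": np.full(100, 1.5),
        }
        toward = compute_outcomes(make_record(traj, direction="toward", condition="toward"), None)
        away = compute_outcomes(make_record(traj, direction="away", condition="away"), None)
        # spatial: kept for toward, inverted for away
        assert toward.foot_placement_change == 3.0
        assert away.foot_placement_change == -3.0
        # body-relative: inverted for toward
        assert toward.ankle_eversion_change == -1.5
        assert away.ankle_eversion_change == 1.5

    def test_missing_emg_channel_leaves_other_outcomes(self):
        row = compute_outcomes(make_record({"rel_heel_x": np.full(100, 1.0)}), None)
        assert row.integrated_peroneus_longus_emg_change is None
        assert row.foot_placement_change == 1.0

    def test_non_step1_rejected(self):
        with pytest.raises(ValueError, match="step \\+1"):
            compute_outcomes(make_record({"cop_rel": np.zeros(100)}, step_index=2), None)

    def test_null_pipeline_outcomes_near_zero(self):
        """All gains zero: the seven outcomes vanish through the full chain."""
        import warnings

        from balancegait.pipeline import analyze_trial
        from balancegait.synthetic import WalkerConfig, generate_trial

        cfg = WalkerConfig(
            seed=17,
            cop_shift_gain=0.0,
            fp_shift_gain=0.0,
            eversion_gain=0.0,
            pushoff_gain=0.0,
            hip_abduction_gain=0.0,
            emg_gain_pl=0.0,
            emg_gain_gm=0.0,
            emg_gain_gastroc=0.0,
            marker_noise_sd=0.0,
            angle_noise_sd=0.0,
            emg_noise_sd=0.0,
            moment_noise_sd=0.0,
            fp_noise_sd=0.0,
            gap_rate=0.0,
            com_pos_sd=0.0,
            com_vel_sd=0.0,
        )
        bundle, _ = generate_trial(cfg, n_steps=80)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            analysis = analyze_trial(bundle)
        assert len(analysis.outcomes) >= 3
        # without CoM-state variability the placement model is degenerate;
        # whether it is rejected or fitted on numerical jitter, the
        # model-based outcome must be absent or nil
        si = analysis.outcomes["stimulus_induced_fp_change"]
        assert si.isna().all() or np.abs(si).max() < 0.1
        for col, tol in [
            ("foot_placement_change", 0.1),
            ("integrated_relative_cop_change", 0.2),
            ("ankle_eversion_change", 0.05),
            ("hip_abduction_change", 0.05),
            ("integrated_gluteus_medius_emg_change", 1.0),
            ("integrated_peroneus_longus_emg_change", 1.0),
        ]:
            assert np.abs(analysis.outcomes[col]).max() < tol, col


class TestOnsetEstimation:
    def test_delayed_linear_ramp_recovered_exactly(self):
        n, T, t0 = 100, 1.0, 0.3
        t = np.linspace(0, T, n)
        resp = np.maximum(0.0, t - t0) * 10.0
        Y = np.tile(resp, (5, 1))
        est = estimate_onset(Y, T)
        assert est.onset_ms == pytest.approx(300.0, abs=1.0)

    def test_pure_ramp_from_origin_gives_zero_onset(self):
        t = np.linspace(0, 1, 100)
        Y = np.tile(5.0 * t, (4, 1))
        est = estimate_onset(Y, 1.0)
        assert est.onset_ms == pytest.approx(0.0, abs=5.0)

    def test_negative_going_response_handled(self):
        t = np.linspace(0, 1, 100)
        Y = np.tile(-np.maximum(0.0, t - 0.4) * 8.0, (5, 1))
        est = estimate_onset(Y, 1.0)
        assert est.onset_ms == pytest.approx(400.0, abs=5.0)

    def test_no_exclusion_region_reports_undefined(self, rng):
        Y = rng.standard_normal((6, 100)) * 5.0
        est = estimate_onset(Y, 0.667)
        assert est.onset_ms is None

    def test_noisy_smoothstep_mean_onset_within_20ms(self, rng):
        t0, ramp, gain, T = 0.3, 0.1, 5.0, 0.667
        t = np.linspace(0, T, 100)
        u = np.clip((t - t0) / ramp, 0, 1)
        shape = gain * u * u * (3 - 2 * u)
        errors = []
        for _ in range(50):
            Y = shape + rng.standard_normal((40, 100)) * 1.0
            est = estimate_onset(Y, T)
            if est.onset_ms is not None:
                errors.append(est.onset_ms - 300.0)
        assert len(errors) >= 45
        assert abs(np.mean(errors)) < 20.0


class TestPointwiseCI:
    def test_identical_trajectories_zero_width(self):
        Y = np.tile(np.linspace(0, 1, 100), (5, 1))
        mean, lo, hi = pointwise_ci(Y)
        assert hi - lo == pytest.approx(np.zeros(100), abs=1e-12)

    def test_two_samples_use_one_df_quantile(self):
        Y = np.array([[0.0] * 100, [2.0] * 100])
        mean, lo, hi = pointwise_ci(Y)
        se = np.std(Y[:, 0], ddof=1) / np.sqrt(2)
        q = t_dist.ppf(0.975, 1)
        assert hi[0] - mean[0] == pytest.approx(q * se)

    def test_single_trajectory_rejected(self):
        with pytest.raises(ValueError):
            pointwise_ci(np.zeros((1, 100)))

    def test_coverage_near_95_percent(self, rng):
        hits = 0
        reps = 400
        for _ in range(reps):
            Y = 1.5 + rng.standard_normal((8, 4))
            _, lo, hi = pointwise_ci(Y)
            hits += lo[0] <= 1.5 <= hi[0]
        # binomial 99% band around 0.95 with n=400
        assert abs(hits / reps - 0.95) < 2.58 * np.sqrt(0.95 * 0.05 / reps)
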
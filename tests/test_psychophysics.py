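import numpy as np
import pytest

from compeye.exceptions import (InsufficientDataError, NormalizationError,
                                ValidationError)
from compeye.psychophysics import (WBATrial, analyze_experiment,
                                   bootstrap_detect, contrast_sensitivity,
                                   delta_wba, normalize, relative_change,
                                   spatial_acuity, temporal_acuity,
                                   window_mean)


def make_trial(left, right, direction="left", **kwargs):
    return WBATrial("f1", np.asarray(left, float), np.asarray(right, float),
                    direction=direction, **kwargs)


class TestDeltaWBA:
    def test_equal_traces_give_zeros(self):
        t = make_trial(np.ones(3000), np.ones(3000))
        assert np.allclose(delta_wba(t), 0.0)

    def test_constant_offset_absorbed_by_baseline(self):
        t = make_trial(np.ones(3000) + 0.5, np.ones(3000))
        assert np.allclose(delta_wba(t), 0.0)

    def test_motion_epoch_offset_survives_baseline(self):
        left = np.ones(3000)
        left[200:] += 0.7  # response begins after the 0.2 s still period
        t = make_trial(left, np.ones(3000))
        d = delta_wba(t)
        assert np.allclose(d[:200], 0.0)
        assert np.allclose(d[200:], 0.7)

    def test_rightward_stimulus_sign_folding(self):
        left = np.ones(3000)
        right = np.ones(3000)
        right[200:] += 0.4  # left - right = -0.4 during motion
        t = make_trial(left, right, direction="right")
        assert np.allclose(delta_wba(t)[200:], 0.4)

    def test_direction_swap_negation_symmetry(self):
        rng = np.random.default_rng(0)
        l, r = rng.random(3000), rng.random(3000)
        d_left = delta_wba(make_trial(l, r, "left"))
        d_right = delta_wba(make_trial(r, l, "right"))
        assert np.allclose(d_left, d_right)

    def test_short_trace_rejected(self):
        with pytest.raises(ValidationError):
            delta_wba(make_trial(np.ones(100), np.ones(100)))


class TestWindowMean:
    def test_constant_series(self):
        assert window_mean(np.full(3000, 2.5)) == pytest.approx(2.5)

    def test_linear_ramp(self):
        t = np.arange(3000) / 1000.0
        # ramp 0 -> 1 over [0, 3] s; mean over [0.5, 2.0] s = 1.25 / 3
        assert window_mean(t / 3.0) == pytest.approx(1.25 / 3, abs=1e-3)

    def test_short_series_rejected(self):
        with pytest.raises(ValidationError):
            window_mean(np.ones(1900))


class TestNormalize:
    def test_scaling_to_maximum(self):
        assert normalize({"a": 2.0, "b": 4.0, "c": 8.0}) == {
            "a": 0.25, "b": 0.5, "c": 1.0}

    def test_single_condition(self):
        assert normalize({"only": 5.0}) == {"only": 1.0}

    def test_nonpositive_max_rejected(self):
        with pytest.raises(NormalizationError):
            normalize({"a": -1.0, "b": -0.5})

    def test_idempotence(self):
        once = normalize({"a": 1.0, "b": 3.0, "c": -0.5})
        assert normalize(once) == once


class TestBootstrapDetect:
    def test_zero_variance_point_interval(self):
        out = bootstrap_detect(np.ones(5), rng=0)
        assert out["ci_lower"] == out["ci_upper"] == 1.0
        assert out["detected"]

    def test_too_few_flies(self):
        with pytest.raises(InsufficientDataError):
            bootstrap_detect([1.0, 2.0])

    def test_null_false_positive_rate_calibrated(self):
        rng = np.random.default_rng(42)
        hits = sum(bootstrap_detect(rng.normal(0, 1, 20), n_boot=10_000,
                                    rng=rng)["detected"]
                   for _ in range(1000))
        assert abs(hits / 1000 - 0.005) <= 0.004

    def test_power_on_clear_signal(self):
        rng = np.random.default_rng(7)
        hits = sum(bootstrap_detect(rng.normal(1.0, 0.5, 20), n_boot=2000,
                                    rng=rng)["detected"]
                   for _ in range(200))
        assert hits / 200 > 0.99


class TestThresholds:
    def test_contrast_sensitivity_printed_values(self):
        grid = np.array([0.09, 0.19, 0.32, 0.55, 1.0])
        for c_min, expect in [(0.19, 5.3), (0.32, 3.1), (0.55, 1.8),
                              (1.0, 1.0)]:
            det = grid >= c_min
            out = contrast_sensitivity(grid, det)
            assert out["c_min"] == c_min
            assert out["sensitivity"] == expect

    def test_contrast_nothing_detected(self):
        out = contrast_sensitivity([0.1, 0.5], [False, False])
        assert not out["defined"]

    def test_spatial_acuity_max_detected(self):
        grid = [0.04, 0.06, 0.08, 0.10, 0.13]
        out = spatial_acuity(grid, [True, True, True, True, False])
        assert out["acuity"] == 0.10 and not out["censored"]

    def test_spatial_acuity_censored_at_grid_top(self):
        grid = [0.04, 0.08, 0.13]
        out = spatial_acuity(grid, [True, True, True])
        assert out["acuity"] == 0.13 and out["censored"]

    def test_temporal_acuity_drop_rule(self):
        out = temporal_acuity([5.0, 10.0, 20.0], [1.0, 0.9, 0.3],
                              [True, True, True])
        assert out["acuity"] == 10.0   # 0.9 -> 0.3 is a 67% drop

    def test_temporal_acuity_sixty_percent_drop(self):
        out = temporal_acuity([5.0, 10.0], [1.0, 0.4], [True, True])
        assert out["acuity"] == 5.0

    def test_temporal_acuity_censored_without_drop(self):
        out = temporal_acuity([5.0, 10.0, 20.0], [0.8, 0.9, 1.0],
                              [True, True, True])
        assert out["acuity"] == 20.0 and out["censored"]

    def test_unsorted_grid_rejected(self):
        with pytest.raises(ValidationError):
            spatial_acuity([0.1, 0.05], [True, True])


class TestRelativeChange:
    @pytest.mark.parametrize("a,b,percent", [(10.6, 1.8, 83),
                                             (10.6, 5.3, 50),
                                             (5.3, 3.1, 42),
                                             (10.6, 3.1, 71),
                                             (20.0, 10.0, 50),
                                             (4.0, 4.0, 0)])
    def test_reported_percent(self, a, b, percent):
        frac, pct = relative_change(a, b)
        assert pct == percent
        assert frac == pytest.approx((a - b) / a)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValidationError):
            relative_change(0.0, 1.0)


class TestEndToEnd:
    def test_folding_symmetry_of_summaries(self):
        from compeye.synthetic import WBASimSpec, make_wba_dataset

        res = make_wba_dataset(WBASimSpec(n_flies=6, seed=3), "contrast")
        flipped = []
        for t in res["trials"]:
            flipped.append(WBATrial(
                t.fly_id, t.right, t.left,
                contrast=t.contrast, spatial_frequency=t.spatial_frequency,
                temporal_frequency=t.temporal_frequency,
                direction="right" if t.direction == "left" else "left",
                lighting=t.lighting, experiment=t.experiment))
        t1, _ = analyze_experiment(res["trials"], n_boot=500, rng=1)
        t2, _ = analyze_experiment(flipped, n_boot=500, rng=1)
        assert np.allclose(t1["mean_normalized"], t2["mean_normalized"])
        assert (t1["detected"] == t2["detected"]).all()

    def test_c_min_recovery_rate(self):
        from compeye.synthetic import WBASimSpec, make_wba_dataset

        hits = 0
        for s in range(50):
            res = make_wba_dataset(WBASimSpec(seed=20_000 + s), "contrast")
            _, thr = analyze_experiment(res["trials"], n_boot=10_000,
                                        rng=30_000 + s)
            hits += thr.c_min == res["truth"]["c_min"]
        assert hits >= 45  # >= 90% of 50 seeded runs

    def test_mixed_experiments_need_explicit_kind(self):
        from compeye.synthetic import WBASimSpec, make_wba_dataset

        spec = WBASimSpec(n_flies=3, seed=1)
        trials = (make_wba_dataset(spec, "contrast")["trials"][:3]
                  + make_wba_dataset(spec, "spatial")["trials"][:3])
        with pytest.raises(ValidationError):
            analyze_experiment(trials)
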
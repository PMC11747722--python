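"""Coarse graining, artifact rejection, AMP and moving-correlation behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lungbrain import (ArtifactSpec, TrendSeries, coarse_grain, compute_amp,
                       inject_artifacts, moving_correlation, process_recording,
                       reject_artifacts, simulate_animal, summarize_periods)
from lungbrain.synth import build_design

from conftest import make_recording


def pearson_bruteforce(x, y):
    """Independent sum-based Pearson r (oracle for moving_correlation)."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x)
    syy = sum(v * v for v in y)
    sxy = sum(a * b for a, b in zip(x, y))
    num = n * sxy - sx * sy
    den = ((n * sxx - sx * sx) * (n * syy - sy * sy)) ** 0.5
    return num / den


def make_trend(x, y, valid_x=None, valid_y=None):
    n = len(x)
    data = pd.DataFrame({"X": x, "Y": y})
    valid = pd.DataFrame({
        "X": np.ones(n, bool) if valid_x is None else valid_x,
        "Y": np.ones(n, bool) if valid_y is None else valid_y,
    })
    return TrendSeries(time=(np.arange(n) + 1) * 10.0, data=data, valid=valid)


class TestCoarseGrain:
    def test_constant_channel(self):
        rec = make_recording({"X": np.full(3200, 7.0)}, fs=32.0)
        trend = coarse_grain(rec)
        assert len(trend.data) == 10
        assert np.all(trend.data["X"] == 7.0)
        assert trend.valid["X"].all()

    def test_arithmetic_mean_of_ramp(self):
        rec = make_recording({"X": np.arange(1, 1001, dtype=float)}, fs=100.0)
        trend = coarse_grain(rec)
        assert trend.data["X"].iloc[0] == pytest.approx(500.5)

    def test_trailing_partial_block_dropped(self):
        rec = make_recording({"X": np.zeros(int(25 * 32))}, fs=32.0)
        assert len(coarse_grain(rec).data) == 2

    def test_block_invalid_below_half_valid_samples(self):
        x = np.zeros(640)
        x[:200] = np.nan          # block 0: 62% invalid
        x[320:420] = np.nan       # block 1: 31% invalid
        trend = coarse_grain(make_recording({"X": x}, fs=32.0))
        assert not trend.valid["X"].iloc[0]
        assert trend.valid["X"].iloc[1]

    def test_empty_recording_raises(self):
        with pytest.raises(ValueError):
            coarse_grain(make_recording({"X": np.zeros(0)}, fs=32.0))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-100, 100), min_size=20, max_size=200))
    def test_mean_of_block_means_conserves_raw_mean(self, values):
        n = (len(values) // 10) * 10
        values = np.asarray(values[:n] if n else values * 10, dtype=float)
        if len(values) < 10:
            values = np.tile(values, 10)[:10]
        rec = make_recording({"X": values}, fs=1.0)
        trend = coarse_grain(rec)
        raw_mean = values[: len(trend.data) * 10].mean()
        assert trend.data["X"].mean() == pytest.approx(raw_mean, rel=1e-9,
                                                       abs=1e-9)


class TestRejectArtifacts:
    def test_icp_threshold_rule(self):
        trend = make_trend([5.0, 70.0, -15.0, 20.0], [80.0] * 4)
        trend.data.columns = ["ICP", "ABP"]
        trend.valid.columns = ["ICP", "ABP"]
        out = reject_artifacts(trend)
        assert list(out.valid["ICP"]) == [True, False, False, True]

    def test_cpp_threshold_invalidates_icp(self):
        trend = make_trend([10.0], [200.0])
        trend.data.columns = ["ICP", "ABP"]
        trend.valid.columns = ["ICP", "ABP"]
        out = reject_artifacts(trend)
        assert out.data["CPP"].iloc[0] == pytest.approx(190.0)
        assert not out.valid["ICP"].iloc[0]
        assert not out.valid["CPP"].iloc[0]

    def test_in_range_mask_unchanged(self):
        rng = np.random.default_rng(0)
        icp = rng.uniform(0, 30, 50)
        abp = rng.uniform(60, 120, 50)
        trend = make_trend(icp, abp)
        trend.data.columns = ["ICP", "ABP"]
        trend.valid.columns = ["ICP", "ABP"]
        out = reject_artifacts(trend)
        assert out.valid["ICP"].all() and out.valid["CPP"].all()

    def test_missing_channel_raises(self):
        trend = make_trend([1.0], [2.0])
        with pytest.raises(KeyError):
            reject_artifacts(trend)

    def test_no_revalidation(self):
        trend = make_trend([10.0, 10.0], [80.0, 80.0])
        trend.data.columns = ["ICP", "ABP"]
        trend.valid.columns = ["ICP", "ABP"]
        trend.valid.loc[0, "ICP"] = False
        out = reject_artifacts(trend)
        assert not out.valid["ICP"].iloc[0]


class TestAmp:
    def test_pure_sinusoid_gives_peak_to_peak(self, sinusoid_icp_rec):
        amp = compute_amp(sinusoid_icp_rec, cardiac_hz=1.6)
        assert amp == pytest.approx(4.0, abs=1e-6)

    def test_constant_icp_gives_zero(self):
        rec = make_recording({"ICP": np.full(640, 12.0)}, fs=32.0)
        assert compute_amp(rec, cardiac_hz=1.6) == pytest.approx(0.0, abs=1e-9)

    def test_slow_drift_barely_leaks(self):
        fs = 32.0
        t = np.arange(int(10 * fs)) / fs
        icp = 10 + 2 * np.sin(2 * np.pi * 1.6 * t) + 0.3 * t  # 3 mmHg drift
        rec = make_recording({"ICP": icp}, fs=fs)
        assert compute_amp(rec, cardiac_hz=1.6)[0] == pytest.approx(4.0, abs=0.1)

    def test_beat_method_agrees_on_sinusoid(self, sinusoid_icp_rec):
        amp = compute_amp(sinusoid_icp_rec, cardiac_hz=1.6, method="beat")
        assert amp == pytest.approx(4.0, abs=0.05)

    def test_cardiac_frequency_detected_from_abp(self, sinusoid_icp_rec):
        amp = compute_amp(sinusoid_icp_rec)  # detect 1.6 Hz from ABP
        assert amp == pytest.approx(4.0, abs=1e-3)

    def test_out_of_band_frequency_rejected(self, sinusoid_icp_rec):
        with pytest.raises(ValueError):
            compute_amp(sinusoid_icp_rec, cardiac_hz=8.0)


class TestMovingCorrelation:
    def test_identical_channels_give_clamped_unity(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=60)
        idx = moving_correlation(make_trend(x, x), "X", "Y")
        assert np.allclose(idx["r"], 1.0)
        assert np.allclose(idx["z"], np.arctanh(0.99))

    def test_anticorrelation(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=60)
        idx = moving_correlation(make_trend(x, -x), "X", "Y")
        assert np.allclose(idx["r"], -1.0)

    def test_null_distribution_sd(self):
        """Independent white noise: SD(r) over windows ~ 1/sqrt(29)."""
        rng = np.random.default_rng(3)
        rs = []
        for _ in range(1000):
            x, y = rng.normal(size=30), rng.normal(size=30)
            idx = moving_correlation(make_trend(x, y), "X", "Y")
            rs.append(idx["r"].iloc[0])
        assert np.mean(rs) == pytest.approx(0.0, abs=0.02)
        assert np.std(rs) == pytest.approx(1 / np.sqrt(29), rel=0.12)

    def test_matches_bruteforce_with_gaps(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=90)
        y = 0.5 * x + rng.normal(size=90)
        vx = rng.random(90) > 0.1
        vy = rng.random(90) > 0.1
        trend = make_trend(x, y, vx, vy)
        idx = moving_correlation(trend, "X", "Y")
        for row in idx.itertuples():
            end = int(row.time / 10)
            m = (vx & vy)[end - 30:end]
            if row.valid:
                expected = pearson_bruteforce(list(x[end - 30:end][m]),
                                              list(y[end - 30:end][m]))
                assert row.r == pytest.approx(expected, abs=1e-12)
            else:
                assert m.sum() < 24

    def test_window_below_min_valid_flagged(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=30), rng.normal(size=30)
        vx = np.ones(30, bool)
        vx[:8] = False  # 22 valid pairs < 24
        idx = moving_correlation(make_trend(x, y, vx), "X", "Y")
        assert not idx["valid"].iloc[0]

    def test_constant_window_is_degenerate(self):
        idx = moving_correlation(make_trend(np.ones(30), np.arange(30.0)),
                                 "X", "Y")
        assert not idx["valid"].iloc[0]

    def test_first_update_at_300s_then_every_minute(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=66)
        idx = moving_correlation(make_trend(x, x), "X", "Y")
        assert idx["time"].iloc[0] == pytest.approx(300.0)
        assert np.allclose(np.diff(idx["time"]), 60.0)


def test_rap_unity_when_amp_linear_in_icp():
    icp = np.linspace(10, 20, 60) + np.sin(np.arange(60))
    amp = 1.0 + 0.2 * icp
    trend = make_trend(icp, amp)
    trend.data.columns = ["ICP", "AMP"]
    trend.valid.columns = ["ICP", "AMP"]
    idx = moving_correlation(trend, "AMP", "ICP")
    assert np.allclose(idx["r"], 1.0)


class TestSummaries:
    def test_constant_icp_period_mean(self, fast_cfg):
        from lungbrain.config import CovariateEffects

        cfg = fast_cfg.replace(icp_slow_sd=0.0, amp_base=0.0, amp_slope=0.0,
                               icp_peep_slope=2.0, icp_peep_slope_sd=0.0,
                               covariate_effects=CovariateEffects(0, 0, 0, 0, 0),
                               ).noiseless()
        rec, truth = simulate_animal(cfg, 0)
        design = build_design(cfg, truth.sequence, truth.animal)
        _, _, summary = process_recording(rec, design=design,
                                          cardiac_hz=cfg.cardiac_hz)
        base = summary[summary["label"] == "baseline"]
        assert np.allclose(base["icp"],
                           [truth.baseline_icp,
                            truth.baseline_icp + truth.supine_offset]
                           if base["position"].iloc[0] == "prone"
                           else [truth.baseline_icp + truth.supine_offset,
                                 truth.baseline_icp], atol=1e-9)
        # delta at baseline vs itself is zero; deltas follow the slope exactly
        assert np.allclose(base["d_icp"], 0.0, atol=1e-12)
        inter = summary[summary["label"] == "intervention"]
        assert np.allclose(inter["d_icp"],
                           2.0 * (inter["peep"] - 5.0) / 5.0, atol=1e-9)

    def test_periods_average_only_whole_windows(self, fast_cfg):
        rec, truth = simulate_animal(fast_cfg, 1)
        design = build_design(fast_cfg, truth.sequence, truth.animal)
        _, indices, summary = process_recording(rec, design=design,
                                                cardiac_hz=fast_cfg.cardiac_hz)
        # 6-min period, 5-min window -> at most 2 whole-window updates inside
        assert summary["prx_n"].max() <= 2
        assert summary["prx_n"].min() >= 1


def test_dropout_marks_exactly_overlapping_blocks(fast_cfg):
    """Block-aligned -20 mmHg dropout over 50 s invalidates exactly those
    five 10-s ICP blocks."""
    rec, _ = simulate_animal(fast_cfg, 0)
    rec = inject_artifacts(rec, [ArtifactSpec("ICP", 200.0, 250.0,
                                              "dropout", -20.0)])
    trend = reject_artifacts(coarse_grain(rec))
    bad = ~trend.valid["ICP"].to_numpy()
    expected = (trend.time > 200.0) & (trend.time <= 250.0)
    assert np.array_equal(bad, expected)
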
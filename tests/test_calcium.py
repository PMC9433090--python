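"""Calcium pipelines: smoothing, baseline, dF/F0, peaks, epochs, binning."""

import numpy as np
import pandas as pd
import pytest

from awapipe import calcium
from awapipe import synthetic_data as syn
from awapipe.synthetic_data import LawnGeometry, Recording


def _rec(neuron, background=None, **kw):
    neuron = np.asarray(neuron, dtype=float)
    if background is None:
        background = np.zeros_like(neuron)
    t = np.arange(neuron.size) / 10.0
    return Recording(t, neuron, background, **kw)


class TestSubtractBackground:
    def test_constant_offset(self):
        rec = _rec(np.full(30, 100.0), np.full(30, 20.0))
        assert np.allclose(calcium.subtract_background(rec), 80.0)

    def test_equal_series_give_zero(self):
        rec = _rec(np.arange(30.0), np.arange(30.0))
        assert np.allclose(calcium.subtract_background(rec), 0.0)

    def test_matches_naive_loop(self):
        rng = np.random.default_rng(3)
        n, b = rng.random(50), rng.random(50)
        rec = _rec(n, b)
        out = calcium.subtract_background(rec)
        for i in range(50):
            assert out[i] == n[i] - b[i]


class TestMovingMedian:
    def test_constant_series_unchanged(self):
        assert np.allclose(calcium.moving_median(np.full(25, 3.0)), 3.0)

    def test_impulse_removed(self):
        x = np.full(40, 2.0)
        x[20] = 100.0
        out = calcium.moving_median(x, window=10)
        assert out[20] == 2.0

    def test_matches_naive_per_index_oracle(self):
        rng = np.random.default_rng(8)
        x = rng.random(67)
        for window in (1, 3, 10, 11):
            out = calcium.moving_median(x, window=window)
            left, right = (window - 1) // 2, window // 2
            for i in range(67):
                chunk = sorted(x[max(0, i - left):min(67, i + right + 1)])
                k = len(chunk)
                med = chunk[k // 2] if k % 2 else (chunk[k // 2 - 1] + chunk[k // 2]) / 2
                assert out[i] == pytest.approx(med)

    def test_idempotent_on_monotone_series_interior(self):
        """Away from the truncated edge windows, re-smoothing a monotone
        series changes nothing (interior idempotence)."""
        x = np.linspace(0, 5, 40)
        once = calcium.moving_median(x, 5)
        twice = calcium.moving_median(once, 5)
        assert np.allclose(once[5:-5], twice[5:-5])

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            calcium.moving_median(np.array([]))


class TestPercentileBaseline:
    def test_constant(self):
        assert calcium.percentile_baseline(np.full(30, 4.0)) == 4.0

    def test_dominant_low_value(self):
        x = np.array([1.0] * 95 + [10.0] * 5)
        assert calcium.percentile_baseline(x) == pytest.approx(1.0)

    def test_matches_sort_interpolation_oracle(self):
        rng = np.random.default_rng(4)
        x = rng.random(83) + 0.5
        srt = np.sort(x)
        pos = 0.05 * (83 - 1)
        lo, hi = int(np.floor(pos)), int(np.ceil(pos))
        expected = srt[lo] + (pos - lo) * (srt[hi] - srt[lo])
        assert calcium.percentile_baseline(x, 5) == pytest.approx(expected)

    def test_non_positive_baseline_rejected(self):
        with pytest.raises(ValueError):
            calcium.percentile_baseline(np.array([-1.0] * 50 + [5.0] * 50))


class TestComputeDff:
    def test_flat_trace_gives_zero(self):
        rec = _rec(np.full(60, 50.0))
        trace = calcium.compute_dff(rec)
        assert np.allclose(trace.dff, 0.0)
        assert trace.baseline == 50.0

    def test_doubling_gives_dff_one(self):
        x = np.full(200, 50.0)
        x[100:130] = 100.0
        trace = calcium.compute_dff(_rec(x))
        assert trace.dff.max() == pytest.approx(1.0)

    def test_noise_free_transient_amplitude(self):
        """Planted unit transient reads out at ~1.0 dF/F0; the residual gap
        is the known moving-median flattening of the sampled kernel."""
        tr = syn.TransientTruth(10.0, 1.0)
        rec, _ = syn.gen_gcamp_recording(duration=60, transients=[tr],
                                         noise_sd=0, seed=0)
        trace = calcium.compute_dff(rec)
        # oracle: median of the sampled kernel inside the centered window
        kern = syn.transient_kernel(rec.time, tr)
        i = int(np.argmax(kern))
        expected = np.median(kern[i - 4:i + 6])
        assert trace.dff.max() == pytest.approx(expected, abs=0.02)
        assert abs(trace.dff.max() - 1.0) < 0.08

    def test_dff_floor_minus_one(self):
        rng = np.random.default_rng(0)
        rec = _rec(np.abs(rng.normal(50, 10, 300)) + 1)
        trace = calcium.compute_dff(rec)
        assert trace.dff.min() >= -1.0

    def test_baseline_percentile_property(self):
        rng = np.random.default_rng(1)
        rec = _rec(rng.uniform(10, 20, 500))
        trace = calcium.compute_dff(rec)
        frac_below = (trace.smoothed < trace.baseline).mean()
        assert frac_below <= 0.055


class TestDetectPeaks:
    def test_flat_trace_no_peaks(self):
        trace = calcium.compute_dff(_rec(np.full(100, 10.0)))
        assert calcium.detect_peaks(trace) == []

    def test_single_transient_one_peak(self):
        rec, _ = syn.gen_gcamp_recording(
            duration=60, transients=[syn.TransientTruth(20.0, 1.0)],
            noise_sd=0, seed=0)
        peaks = calcium.detect_peaks(calcium.compute_dff(rec))
        assert len(peaks) == 1
        assert peaks[0].time == pytest.approx(20.9, abs=0.5)
        assert peaks[0].end > peaks[0].start

    def test_fwhm_duration(self):
        """A triangular bump's FWHM spans the frames above half-peak."""
        x = np.full(200, 10.0)
        x[100:111] = 10.0 + np.array([2, 4, 6, 8, 10, 12, 10, 8, 6, 4, 2])
        trace = calcium.compute_dff(_rec(x), window=1)
        peaks = calcium.detect_peaks(trace, min_amplitude=0.5)
        assert len(peaks) == 1
        p = peaks[0]
        half = p.amplitude / 2
        assert all(trace.dff[p.start:p.end + 1] >= half)
        assert trace.dff[p.start - 1] < half and trace.dff[p.end + 1] < half

    def test_amplitude_monotone_in_planted_amplitude(self):
        amps = [0.3, 0.6, 1.2, 2.4]
        detected = []
        for a in amps:
            rec, _ = syn.gen_gcamp_recording(
                duration=40, transients=[syn.TransientTruth(10.0, a)],
                noise_sd=0, seed=0)
            peaks = calcium.detect_peaks(calcium.compute_dff(rec),
                                         min_amplitude=0.1)
            detected.append(max(p.amplitude for p in peaks))
        assert all(d2 > d1 for d1, d2 in zip(detected, detected[1:]))


class TestMicrofluidic:
    def test_flat_trace_zero_everywhere(self):
        f = np.full(300, 50.0)
        percent, pre, stim, post = calcium.microfluidic_percent_change(f)
        assert np.allclose(percent, 0.0)
        assert pre == stim == post == 0.0

    def test_stim_only_step(self):
        t = np.arange(300) / 10.0
        f = np.full(300, 100.0)
        f[(t >= 6) & (t <= 14)] = 150.0
        percent, pre, stim, post = calcium.microfluidic_percent_change(f, time=t)
        assert stim == pytest.approx(50.0)
        assert pre == 0.0 and post == 0.0

    def test_sample_at_exactly_5s_counts_in_stim(self):
        t = np.arange(300) / 10.0
        f = np.full(300, 100.0)
        f[t == 5.0] = 200.0  # unique maximum exactly at the Stim lower bound
        _, pre, stim, _ = calcium.microfluidic_percent_change(f, time=t)
        assert stim == pytest.approx(100.0)
        assert pre == pytest.approx(0.0)

    def test_gap_frames_belong_to_no_epoch(self):
        t = np.arange(300) / 10.0
        f = np.full(300, 100.0)
        f[np.isclose(t, 4.95)] = 500.0
        # 4.95 s is in neither Pre (ends 4.9) nor Stim (starts 5.0);
        # with the 10 fps grid there is no such sample, so use a 20 fps grid
        t = np.arange(600) / 20.0
        f = np.full(600, 100.0)
        f[np.isclose(t, 4.95)] = 500.0
        _, pre, stim, _ = calcium.microfluidic_percent_change(f, time=t)
        assert pre == pytest.approx(0.0) and stim == pytest.approx(0.0)

    def test_non_positive_f0_rejected(self):
        with pytest.raises(ValueError):
            calcium.microfluidic_percent_change(np.full(300, 0.0))


class TestDistanceAndBinning:
    def test_signed_distance_convention(self):
        lawn = LawnGeometry((0.0, 0.0), 2.0)
        pos = np.array([[0.0, 0.0], [2.0, 0.0], [3.3, 0.0]])
        d = calcium.distance_to_lawn(pos, lawn)
        assert d[0] == pytest.approx(-2.0)
        assert d[1] == pytest.approx(0.0)
        assert d[2] == pytest.approx(1.3)

    def test_bin_assignment(self):
        d = np.array([0.2, 0.7, 1.2])
        out = calcium.bin_dff_by_distance(np.ones(3), d)
        assert out["bin_left"].tolist() == [0.0, 0.5, 1.0]
        assert out["n"].tolist() == [1, 1, 1]

    def test_constant_dff_constant_bins(self):
        rng = np.random.default_rng(2)
        d = rng.uniform(-1, 2, 200)
        out = calcium.bin_dff_by_distance(np.full(200, 0.7), d)
        occupied = out[out["n"] > 0]
        assert np.allclose(occupied["mean"], 0.7)

    def test_matches_groupby_oracle(self):
        rng = np.random.default_rng(5)
        dff = rng.normal(size=300)
        d = rng.uniform(-2, 3, 300)
        out = calcium.bin_dff_by_distance(dff, d).set_index("bin_left")
        df = pd.DataFrame({"dff": dff, "bin": np.floor(d / 0.5) * 0.5})
        for b, sub in df.groupby("bin"):
            assert out.loc[b, "mean"] == pytest.approx(sub["dff"].mean())
            assert out.loc[b, "n"] == len(sub)
            if len(sub) > 1:
                assert out.loc[b, "sem"] == pytest.approx(
                    sub["dff"].std(ddof=1) / np.sqrt(len(sub)))

    def test_empty_bins_reported(self):
        d = np.array([0.1, 2.1])
        out = calcium.bin_dff_by_distance(np.ones(2), d)
        assert (out["n"] == 0).sum() == 3


class TestStateAnova:
    def _binned(self, offset, noise, seed):
        rng = np.random.default_rng(seed)
        rows = []
        for state, shift in (("fed", 0.0), ("fasted", offset)):
            for a in range(6):
                for b in np.arange(0, 2, 0.5):
                    rows.append({"animal": f"{state}{a}", "state": state,
                                 "bin": b,
                                 "value": shift + rng.normal(0, noise)})
        return pd.DataFrame(rows)

    def test_identical_groups_null(self):
        df = self._binned(0.0, 0.05, 0)
        res = calcium.state_effect_anova(df)
        assert res["state"][1] > 0.01

    def test_planted_state_offset_detected(self):
        hits = 0
        for seed in range(20):
            res = calcium.state_effect_anova(self._binned(0.5, 0.1, seed))
            hits += res["state"][1] < 0.01
        assert hits >= 19

    def test_fed_vs_fasted_amplitude_pattern(self):
        """Fasted recordings with 2x transient amplitude give larger binned
        signal near the lawn and a significant state effect."""
        rows = []
        for j, state in enumerate(["fed"] * 5 + ["fasted"] * 5):
            scale = 1.0 if state == "fed" else 2.0
            rng = np.random.default_rng(100 + j)
            trs = [syn.TransientTruth(float(t), float(rng.uniform(0.4, 0.8) * scale))
                   for t in (10, 30, 50, 70, 90)]
            rec, _ = syn.gen_gcamp_recording(duration=110, transients=trs,
                                             noise_sd=1.0, seed=200 + j)
            trace = calcium.compute_dff(rec)
            dist = calcium.distance_to_lawn(rec.position, rec.lawn)
            binned = calcium.bin_dff_by_distance(trace.dff, dist)
            for r in binned.itertuples():
                if r.n > 0 and -1.0 <= r.bin_left <= 1.5:
                    rows.append({"animal": f"a{j}", "state": state,
                                 "bin": r.bin_left, "value": r.mean})
        df = pd.DataFrame(rows)
        means = df.groupby("state")["value"].mean()
        assert means["fasted"] > means["fed"]
        res = calcium.state_effect_anova(df)
        assert res["state"][1] < 0.05
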
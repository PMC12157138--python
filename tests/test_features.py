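"""Derivative stack, fiducials, and the 218-feature extractor."""

import numpy as np
import pandas as pd
import pytest

from ppgcausal import registry, signals, synthetic
from ppgcausal.exceptions import InsufficientData, InvalidInput
from ppgcausal.features import (
    BeatFiducials,
    DerivativeStack,
    build_feature_table,
    derivatives,
    detect_fiducials,
    deviation_features,
    extract_features,
    fft_features,
    histogram_features,
    index_features,
    time_features,
)


class TestRegistry:
    def test_exactly_218_unique_names(self):
        names = registry.feature_names()
        assert len(names) == 218
        assert len(set(names)) == 218

    def test_category_slot_counts(self):
        reg = registry.feature_registry()
        counts = {}
        for _, cat in reg:
            counts[cat] = counts.get(cat, 0) + 1
        assert counts == {
            "frequency": 3,
            "poi": 27,
            "interval": 28,
            "area": 12,
            "cyclicality": 21,
            "width": 21,
            "sqi": 2,
            "index": 4,
            "deviation": 25,
            "histogram": 75,
        }

    def test_registry_stable_across_calls(self):
        assert registry.feature_names() == registry.feature_names()


class TestDerivatives:
    def test_linear_ramp(self):
        fs = 125.0
        x = 0.3 * np.arange(500) / fs
        stack = derivatives(x, fs)
        mid = slice(10, 490)
        np.testing.assert_allclose(stack.vpg[mid], 0.3, atol=1e-9)
        np.testing.assert_allclose(stack.apg[mid], 0.0, atol=1e-9)

    def test_sine_analytic_derivative(self):
        fs, f = 125.0, 1.2
        t = np.arange(2000) / fs
        stack = derivatives(np.sin(2 * np.pi * f * t), fs)
        mid = slice(100, 1900)
        expected = 2 * np.pi * f * np.cos(2 * np.pi * f * t[mid])
        err = np.abs(stack.vpg[mid] - expected).max() / (2 * np.pi * f)
        assert err < 0.02

    def test_stack_has_five_signals(self):
        stack = derivatives(np.random.default_rng(0).standard_normal(100))
        assert len(stack.signals) == 5
        assert all(sig.size == 100 for sig in stack.signals.values())

    def test_too_short_rejected(self):
        with pytest.raises(InvalidInput):
            derivatives(np.zeros(4))


@pytest.fixture(scope="module")
def fiducial_setup(clean_segment):
    segment, truth = clean_segment
    stack = derivatives(segment.ppg, segment.fs)
    fset = detect_fiducials(stack, segment.onsets, segment.fs)
    return segment, truth, stack, fset


class TestDetectFiducials:
    CORE = [("sys", "sys_peak"), ("w", "w"), ("y", "y"), ("a", "a"), ("b", "b"),
            ("notch", "notch"), ("dia", "dia_peak"), ("z", "z")]
    LATE = [("c", "c"), ("d", "d"), ("e", "e")]

    def test_core_fiducials_recovered(self, fiducial_setup):
        _, truth, _, fset = fiducial_setup
        assert len(fset) >= 25
        for name, attr in self.CORE:
            det = np.array(
                [getattr(b, attr) for b in fset.beats if getattr(b, attr) is not None]
            )
            covered = [
                t for t in truth.fiducials[name] if det.min() - 3 <= t <= det.max() + 3
            ]
            errors = [np.min(np.abs(det - t)) for t in covered]
            assert np.median(errors) <= 2, name

    def test_late_apg_waves_recovered_coarsely(self, fiducial_setup):
        # 3rd/4th-derivative extrema in late diastole are noise-limited
        _, truth, _, fset = fiducial_setup
        for name, attr in self.LATE:
            det = np.array(
                [getattr(b, attr) for b in fset.beats if getattr(b, attr) is not None]
            )
            covered = [
                t for t in truth.fiducials[name] if det.min() - 6 <= t <= det.max() + 6
            ]
            errors = [np.min(np.abs(det - t)) for t in covered]
            assert np.median(errors) <= 5, name

    def test_w_is_vpg_argmax_in_upstroke(self, fiducial_setup):
        _, _, stack, fset = fiducial_setup
        for beat in fset.beats[:5]:
            lo = max(beat.onset + 3, beat.onset)
            window = stack.vpg[lo : beat.sys_peak + 1]
            assert stack.vpg[beat.w] == pytest.approx(window.max())

    def test_apg_waves_temporally_ordered(self, fiducial_setup):
        _, _, _, fset = fiducial_setup
        for beat in fset.beats:
            seq = [beat.a, beat.b, beat.c, beat.d, beat.e]
            present = [s for s in seq if s is not None]
            assert present == sorted(present)
            assert beat.onset < beat.sys_peak

    def test_flat_beat_skipped(self):
        stack = derivatives(np.zeros(500))
        fset = detect_fiducials(stack, np.array([0, 125, 250]))
        assert len(fset) == 0 and len(fset.skipped) == 2


class TestFFTFeatures:
    def test_pure_tone_peak(self):
        fs = 125.0
        t = np.arange(int(30 * fs)) / fs
        freq, height, _ = fft_features(np.sin(2 * np.pi * 1.2 * t), fs)
        assert abs(freq - 1.2) <= 1.0 / 30 + 1e-9  # within one bin
        assert height > 0

    def test_zero_signal(self):
        assert fft_features(np.zeros(256)) == (0.0, 0.0, 0.0)

    def test_neighborhood_mean_brute_force(self, rng):
        fs = 125.0
        x = rng.standard_normal(1024) + np.sin(2 * np.pi * 2.0 * np.arange(1024) / fs)
        _, _, neigh = fft_features(x, fs)
        mag = np.abs(np.fft.rfft(x - x.mean()))
        freqs = np.fft.rfftfreq(1024, 1 / fs)
        band = np.nonzero((freqs >= 0.5) & (freqs <= 10.0))[0]
        pk = band[np.argmax(mag[band])]
        assert neigh == pytest.approx(mag[max(0, pk - 3) : pk + 4].mean(), rel=1e-12)

    def test_short_signal_rejected(self):
        with pytest.raises(InvalidInput):
            fft_features(np.zeros(64))


class TestTimeFeatures:
    def test_area_fractions_sum_to_one(self, fiducial_setup):
        _, _, stack, fset = fiducial_setup
        table = time_features(fset, stack)
        sums = table[["s1_frac", "s2_frac", "s3_frac", "s4_frac"]].sum(axis=1)
        np.testing.assert_allclose(sums.dropna(), 1.0, atol=1e-9)

    def test_symmetric_triangle_equal_widths(self):
        # symmetric triangular pulse: systolic and diastolic widths match
        rise = np.linspace(0.0, 1.0, 51)
        beat = np.concatenate([rise, rise[-2::-1]])
        x = np.tile(beat[:-1], 4)
        stack = DerivativeStack(x, *[np.zeros_like(x)] * 4)
        onsets = np.arange(5) * 100
        fid = BeatFiducials(
            onset=100, next_onset=200, sys_peak=150, w=125, y=175, a=110, b=120,
            tc=100 / 125.0,
        )
        fset_like = type("F", (), {"beats": [fid]})()
        table = time_features(fset_like, stack)
        assert table.loc[0, "sw50_s"] == pytest.approx(table.loc[0, "dw50_s"], abs=2 / 125)

    def test_widths_match_exhaustive_scan(self, fiducial_setup):
        segment, _, stack, fset = fiducial_setup
        fs = segment.fs
        table = time_features(fset, stack)
        for i, fid in enumerate(fset.beats[:5]):
            base = stack.ppg[fid.onset]
            amp = stack.ppg[fid.sys_peak] - base
            for lvl in (25, 75):
                level = base + lvl / 100 * amp
                rise_idx = [
                    j for j in range(fid.onset, fid.sys_peak + 1)
                    if stack.ppg[j] >= level
                ]
                fall_idx = [
                    j for j in range(fid.sys_peak, fid.next_onset)
                    if stack.ppg[j] >= level
                ]
                assert table.loc[i, f"sw{lvl}_s"] == pytest.approx(
                    (fid.sys_peak - rise_idx[0]) / fs
                )
                assert table.loc[i, f"dw{lvl}_s"] == pytest.approx(
                    (fall_idx[-1] - fid.sys_peak) / fs
                )

    def test_tc_normalized_intervals_time_rescaling_invariant(self):
        # same template at double the period: normalized intervals agree
        vals = {}
        for hr in (60.0, 30.0):
            record, _ = synthetic.gen_ppg(
                hr_bpm=hr, n_beats=12, noise_sd=0.0, drift_amp=0.0, seed=0
            )
            stack = derivatives(record.ppg)
            onsets = np.arange(12) * int(125 * 60 / hr)
            table = time_features(detect_fiducials(stack, onsets), stack)
            vals[hr] = table[["t_on_sys_norm", "t_on_notch_norm", "t_sys_notch_norm"]].median()
        for col in vals[60.0].index:
            assert vals[60.0][col] == pytest.approx(vals[30.0][col], rel=0.02, abs=0.01)


class TestDeviationFeatures:
    def _fid(self, onset, sys_peak, nxt):
        return BeatFiducials(
            onset=onset, next_onset=nxt, sys_peak=sys_peak, w=onset + 1,
            y=sys_peak + 1, a=onset + 1, b=onset + 2, tc=(nxt - onset) / 125.0,
        )

    def test_linear_edges_give_zero_curves(self):
        x = np.concatenate([np.linspace(0, 1, 26), np.linspace(1, 0, 75)[1:]])
        out = deviation_features(x, self._fid(0, 25, 100))
        for stat in registry.DEVIATION_STATS:
            assert out[f"usdc_{stat}"] == pytest.approx(0.0, abs=1e-9)
            assert out[f"dsdc_{stat}"] == pytest.approx(0.0, abs=1e-9)

    def test_quadratic_edge_matches_brute_force(self):
        t = np.linspace(0, 1, 26)
        rise = t**2
        x = np.concatenate([rise, np.linspace(1, 0, 75)])
        out = deviation_features(x, self._fid(0, 25, 100))
        slope = (rise[-1] - rise[0]) / 25
        curve = rise - (rise[0] + slope * np.arange(26))
        assert out["usdc_max"] == pytest.approx(curve.max())
        assert out["usdc_min"] == pytest.approx(curve.min())
        assert out["usdc_mean"] == pytest.approx(curve.mean())
        assert out["usdc_rms"] == pytest.approx(np.sqrt(np.mean(curve**2)))
        assert out["usdc_argmin_norm"] == pytest.approx(np.argmin(curve) / 100)

    def test_degenerate_edge_gives_zeros(self):
        x = np.linspace(0, 1, 100)
        out = deviation_features(x, self._fid(0, 1, 100))  # 2-sample rising edge
        assert out["usdc_rms"] == 0.0


class TestIndexFeatures:
    def _stack_with_apg(self, apg_vals, sys_amp=1.0):
        n = 20
        ppg = np.zeros(n)
        ppg[5] = sys_amp
        apg = np.zeros(n)
        for i, v in enumerate(apg_vals):
            apg[6 + i] = v
        zero = np.zeros(n)
        return DerivativeStack(ppg, zero, apg, zero, zero)

    def _fid(self):
        return BeatFiducials(
            onset=0, next_onset=19, sys_peak=5, w=2, y=7, a=6, b=7, c=8, d=9, e=10,
            tc=19 / 125.0,
        )

    def test_hand_arithmetic(self):
        stack = self._stack_with_apg([1.0, -0.5, -0.2, -0.3, 0.1])
        out = index_features(self._fid(), stack)
        assert out["aging_index"] == pytest.approx(-0.1)
        assert out["ibd_index"] == pytest.approx((-0.5 + 0.3) / 1.0)
        assert out["ibcda_index"] == pytest.approx((-0.5 + 0.2 + 0.3) / 1.0)
        assert out["isdoo_index"] == pytest.approx((1.0 + 0.3) / 1.0)

    def test_zero_b_c_d_e(self):
        stack = self._stack_with_apg([1.0, 0.0, 0.0, 0.0, 0.0])
        assert index_features(self._fid(), stack)["aging_index"] == pytest.approx(0.0)

    def test_zero_a_wave_missing(self):
        stack = self._stack_with_apg([0.0, -0.5, -0.2, -0.3, 0.1])
        assert np.isnan(index_features(self._fid(), stack)["aging_index"])


class TestHistogramFeatures:
    def test_masses_sum_to_one_per_signal(self, fiducial_setup):
        _, _, stack, _ = fiducial_setup
        out = histogram_features(stack)
        assert len(out) == 75
        for sig in registry.SIGNALS:
            total = sum(out[f"hist_{sig}_{i:02d}"] for i in range(15))
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_uniform_signal_equal_bins(self, rng):
        x = rng.uniform(0, 1, 100_000)
        zero = np.zeros_like(x)
        out = histogram_features(DerivativeStack(x, zero + 1, zero + 2, zero + 3, zero + 4))
        for i in range(15):
            assert out[f"hist_ppg_{i:02d}"] == pytest.approx(1 / 15, abs=0.01)

    def test_constant_signal_single_bin(self):
        x = np.full(100, 2.0)
        out = histogram_features(DerivativeStack(x, x, x, x, x))
        assert out["hist_ppg_00"] == 1.0
        assert sum(out[f"hist_ppg_{i:02d}"] for i in range(1, 15)) == 0.0


class TestExtractFeatures:
    def test_length_and_names(self, clean_segment):
        vec = extract_features(clean_segment[0])
        assert len(vec) == 218
        assert list(vec.index) == registry.feature_names()
        assert vec.notna().all()

    def test_two_identical_beats_same_medians(self):
        beat = synthetic.ppg_beat_template(125)
        for n_beats in (2, 4):
            # pad beats on both ends so every measured beat is interior
            # (away from the derivative-smoothing edge effects)
            x = np.tile(beat, n_beats + 2)
            seg = signals.CleanSegment(
                ppg=x, onsets=(np.arange(n_beats + 1) + 1) * 125, sqi_skew=0.2,
                sqi_kurtosis=2.0, sbp=120, dbp=80, subject_id="s",
            )
            if n_beats == 2:
                first = extract_features(seg)
            else:
                second = extract_features(seg)
        poi_cols = [n for n, c in registry.feature_registry() if c in ("poi", "interval")]
        pd.testing.assert_series_equal(first[poi_cols], second[poi_cols], atol=1e-9)

    def test_offset_invariance_of_onset_referenced_amplitudes(self, clean_segment):
        segment, _ = clean_segment
        shifted = signals.CleanSegment(
            ppg=segment.ppg + 5.0, onsets=segment.onsets, sqi_skew=segment.sqi_skew,
            sqi_kurtosis=segment.sqi_kurtosis, sbp=segment.sbp, dbp=segment.dbp,
            subject_id=segment.subject_id,
        )
        a = extract_features(segment)
        b = extract_features(shifted)
        poi = [n for n, c in registry.feature_registry() if c == "poi"]
        np.testing.assert_allclose(a[poi], b[poi], atol=1e-8)

    def test_unusable_segment_raises(self):
        seg = signals.CleanSegment(
            ppg=np.zeros(500), onsets=np.array([0, 125, 250]), sqi_skew=0.0,
            sqi_kurtosis=3.0, sbp=120, dbp=80, subject_id="s",
        )
        with pytest.raises(InsufficientData):
            extract_features(seg)

    def test_feature_table_layout(self, clean_segment):
        table = build_feature_table([clean_segment[0]] * 3, dataset_id="dX")
        assert table.shape == (3, 222)
        assert list(table.columns[-4:]) == ["sbp", "dbp", "subject_id", "dataset"]
        assert (table["dataset"] == "dX").all()
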
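import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sparpaf as sp
from sparpaf.exceptions import (
    ConfigurationError,
    DegenerateSignalError,
    InsufficientBeatsError,
    StripSelectionError,
)

FS = 500.0


def _corrupt(seg, fs, kind, rng):
    t = np.arange(len(seg)) / fs
    if kind == "wander":
        return seg + 3.0 * np.sin(2 * np.pi * 0.2 * t) + np.cumsum(rng.standard_normal(len(seg))) * 0.02
    burst = seg.copy()
    n = len(seg)
    burst[n // 6 : n // 2] += 4.0 * rng.standard_normal(n // 2 - n // 6)
    return burst


class TestQualityScore:
    def test_clean_beats_corrupted(self, clean_record):
        rng = np.random.default_rng(0)
        seg = clean_record.samples[: int(60 * FS)]
        clean = sp.score_strip_quality(seg, FS)
        for kind in ("wander", "burst"):
            assert clean > sp.score_strip_quality(_corrupt(seg, FS, kind, rng), FS)

    def test_deterministic(self, clean_record):
        seg = clean_record.samples[: int(60 * FS)]
        assert sp.score_strip_quality(seg, FS) == sp.score_strip_quality(seg, FS)

    def test_flatline_gets_finite_minimum(self):
        s = sp.score_strip_quality(np.zeros(int(60 * FS)), FS)
        assert np.isfinite(s) and s < 0

    def test_too_short_rejected(self):
        with pytest.raises(ConfigurationError):
            sp.score_strip_quality(np.zeros(100), FS)


class TestSelectStrips:
    def test_clean_record_one_strip_per_third(self, clean_record):
        strips = sp.select_strips(clean_record)
        assert len(strips) == 3
        third = len(clean_record.samples) / 3
        starts = [s for s, _, _ in strips]
        assert starts == sorted(starts)
        for k, start in enumerate(starts):
            assert k * third <= start and start + 60 * FS <= (k + 1) * third + 1

    def test_fallback_into_clean_prefix(self):
        """Artefacts everywhere except the first 4 minutes force the fallback."""
        spec = sp.CohortSpec(
            n_control=1, n_paf=0, record_len=600, wander_amp=0.0,
            hf_noise_snr=np.inf, artefact_rate_per_hour=0.0, seed=3,
        )
        tpl = sp.make_beat_template(1, 0.0, seed=3)
        rec = sp.generate_record(tpl, spec, "control", seed=3)
        rng = np.random.default_rng(1)
        noisy = rec.samples.copy()
        cut = int(240 * FS)
        noisy[cut:] += 4.0 * rng.standard_normal(len(noisy) - cut)
        rec = sp.EcgSignal("fallback", "control", FS, noisy)
        strips = sp.select_strips(rec)
        assert len(strips) == 3
        for start, _, _ in strips:
            assert start + 60 * FS <= cut + FS

    def test_short_record_rejected(self):
        rec = sp.EcgSignal("short", "control", FS, np.random.default_rng(0).normal(size=int(170 * FS)))
        with pytest.raises(StripSelectionError):
            sp.select_strips(rec)

    def test_strips_never_overlap(self, clean_record):
        strips = sp.select_strips(clean_record)
        starts = sorted(s for s, _, _ in strips)
        assert all(b - a >= 60 * FS for a, b in zip(starts, starts[1:]))


class TestSplitSubstrips:
    def test_sizes_at_500hz(self):
        segs = sp.split_substrips(np.zeros(30000), FS)
        assert [len(s) for s in segs] == [10000, 10000, 10000]

    def test_partition_reconstructs_strip(self, clean_record):
        strip = clean_record.samples[:30000]
        segs = sp.split_substrips(strip, FS)
        assert np.array_equal(np.concatenate(segs), strip)

    def test_wrong_length_rejected(self):
        with pytest.raises(ConfigurationError):
            sp.split_substrips(np.zeros(25000), FS)


class TestFilterEcg:
    def test_constant_removed(self):
        out = sp.filter_ecg(np.full(20000, 7.3), FS)
        assert np.max(np.abs(out)) < 1e-6 * 7.3

    def test_passband_sinusoid_preserved(self):
        t = np.arange(20000) / FS
        x = np.sin(2 * np.pi * 10.0 * t)
        y = sp.filter_ecg(x, FS)
        rms_ratio = np.sqrt(np.mean(y[2000:-2000] ** 2) / np.mean(x[2000:-2000] ** 2))
        assert 0.85 < rms_ratio < 1.15

    def test_stopband_sinusoid_attenuated(self):
        t = np.arange(20000) / FS
        x = np.sin(2 * np.pi * 80.0 * t)
        y = sp.filter_ecg(x, FS)
        rms_ratio = np.sqrt(np.mean(y[2000:-2000] ** 2) / np.mean(x[2000:-2000] ** 2))
        assert rms_ratio < 10 ** (-40 / 20)

    def test_zero_phase_keeps_peak_timing(self, clean_record):
        seg = clean_record.samples[:10000]
        peak_in = int(np.argmax(np.abs(seg - np.median(seg))))
        out = sp.filter_ecg(seg, FS)
        peak_out = int(np.argmax(np.abs(out)))
        assert abs(peak_in - peak_out) <= 1

    def test_infeasible_cutoffs_named(self):
        with pytest.raises(ConfigurationError, match="lp_stopband_edge"):
            sp.filter_ecg(np.zeros(20000), 100.0, sp.FilterSpec(lp_stopband_edge=60.0))


class TestNormalize:
    def test_scale_invariance(self):
        x = np.random.default_rng(0).normal(size=5000)
        assert np.allclose(sp.normalize_amplitude(7 * x), sp.normalize_amplitude(x))

    def test_percentile_is_one(self):
        x = np.random.default_rng(1).normal(size=5000)
        out = sp.normalize_amplitude(x)
        assert np.isclose(np.percentile(np.abs(out), 99.9), 1.0)

    def test_odd_symmetry(self):
        x = np.random.default_rng(2).normal(size=5000)
        assert np.allclose(sp.normalize_amplitude(-x), -sp.normalize_amplitude(x))

    def test_degenerate_rejected(self):
        with pytest.raises(DegenerateSignalError):
            sp.normalize_amplitude(np.zeros(100))

    @settings(deadline=None, max_examples=25)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance_property(self, scale):
        x = np.random.default_rng(3).normal(size=1000)
        assert np.allclose(sp.normalize_amplitude(scale * x), sp.normalize_amplitude(x))


class TestRPeaks:
    def test_known_beat_count(self):
        spec = sp.CohortSpec(
            n_control=1, n_paf=0, record_len=20, hr_mean=30, rr_jitter_cv=0.0,
            wander_amp=0.0, hf_noise_snr=np.inf, artefact_rate_per_hour=0.0,
        )
        tpl = sp.make_beat_template(1, 0.0, seed=1)
        rec = sp.generate_record(tpl, spec, "control", seed=1)
        peaks = sp.detect_r_peaks(rec.samples, FS)
        assert abs(len(peaks) - 10) <= 1

    def test_negation_invariance(self, clean_substrip):
        peaks = sp.detect_r_peaks(clean_substrip.samples, FS)
        peaks_neg = sp.detect_r_peaks(-clean_substrip.samples, FS)
        assert np.array_equal(peaks, peaks_neg)

    def test_strictly_increasing(self, default_substrip):
        peaks = sp.detect_r_peaks(default_substrip.samples, default_substrip.fs)
        assert np.all(np.diff(peaks) > 0)

    def test_flatline_rejected(self):
        with pytest.raises(InsufficientBeatsError):
            sp.detect_r_peaks(np.zeros(10000), FS)


class TestMeanRR:
    def test_arithmetic(self):
        assert sp.mean_rr(np.array([0, 500, 1000]), 500.0) == 1.0
        assert sp.mean_rr(np.array([0, 750, 1500]), 500.0) == 1.5

    def test_matches_brute_force_on_jittered_peaks(self):
        rng = np.random.default_rng(0)
        idx = np.cumsum(rng.integers(300, 900, size=20))
        expected = np.mean(np.diff(idx)) / 500.0
        assert np.isclose(sp.mean_rr(idx, 500.0), expected)

    def test_single_peak_rejected(self):
        with pytest.raises(InsufficientBeatsError):
            sp.mean_rr(np.array([5]), 500.0)


class TestPreprocessSignal:
    def test_count_conservation(self, clean_record):
        subs, excl = sp.preprocess_signal(clean_record)
        assert len(subs) + len(excl) == 9

    def test_substrip_contract(self, default_substrip):
        s = default_substrip
        assert len(s.samples) == round(20 * s.fs)
        assert np.percentile(np.abs(s.samples), 99.9) <= 1.0 + 1e-9
        assert s.mean_rr > 0
        assert np.all(np.diff(s.r_peaks) > 0)

    def test_amplitude_scaling_invariance(self, clean_record):
        """normalize o filter is invariant to input gain and offset."""
        subs1, _ = sp.preprocess_signal(clean_record)
        scaled = sp.EcgSignal("sc", "control", clean_record.fs, 3.5 * clean_record.samples + 2.0)
        subs2, _ = sp.preprocess_signal(scaled)
        assert np.allclose(subs1[0].samples, subs2[0].samples, atol=1e-6)
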
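import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pediecg.io import IECGRecord
from pediecg.segmentation import (
    SegmenterConfig,
    detect_r_peaks,
    frame_beats,
    match_peaks,
    rr_intervals,
    trim_leading_artifact,
)
from pediecg.synthetic import SyntheticSpec, generate_iecg


def _record(samples, fs=512.0, age=8.0):
    return IECGRecord(np.asarray(samples, dtype=float), fs, age, "t")


class TestTrim:
    def test_clean_record_unchanged(self):
        rec, _ = generate_iecg(SyntheticSpec(seed=3, age_years=5, heart_rate_bpm=100))
        out = trim_leading_artifact(rec)
        assert out.n_samples == rec.n_samples
        assert out.metadata["leading_trim_s"] == "0"

    def test_artifact_burst_removes_five_seconds(self):
        rec, _ = generate_iecg(
            SyntheticSpec(seed=3, age_years=5, heart_rate_bpm=100, leading_artifact_s=5.0)
        )
        out = trim_leading_artifact(rec)
        assert rec.n_samples - out.n_samples == 5 * 512
        assert out.metadata["leading_trim_s"] == "5"

    def test_infinite_threshold_never_trims(self):
        rec, _ = generate_iecg(
            SyntheticSpec(seed=3, age_years=5, heart_rate_bpm=100, leading_artifact_s=5.0)
        )
        config = SegmenterConfig(artifact_power_ratio_threshold=np.inf)
        assert trim_leading_artifact(rec, config).n_samples == rec.n_samples

    def test_too_short_record_raises(self):
        with pytest.raises(ValueError, match="trim window"):
            trim_leading_artifact(_record(np.zeros(512)))


class TestDetect:
    def test_flat_signal_yields_no_peaks(self):
        assert len(detect_r_peaks(_record(np.zeros(512 * 5)))) == 0

    def test_noise_free_sixty_bpm_exact(self):
        rec, truth = generate_iecg(
            SyntheticSpec(seed=1, heart_rate_bpm=60, rr_jitter_fraction=0.0,
                          noise_sd_uv=0.0, baseline_wander_uv=0.0, age_years=15)
        )
        peaks = detect_r_peaks(rec)
        matched, n_det, n_truth = match_peaks(peaks, truth.r_peak_indices, 512, 20.0)
        assert matched == n_det == n_truth

    def test_short_record_raises(self):
        with pytest.raises(ValueError, match="1 s"):
            detect_r_peaks(_record(np.ones(100)))

    def test_inversion_and_scaling_invariance(self):
        rec, _ = generate_iecg(SyntheticSpec(seed=11, age_years=8, heart_rate_bpm=90))
        base = detect_r_peaks(rec)
        inverted = _record(-rec.samples)
        assert np.array_equal(base, detect_r_peaks(inverted))
        for scale in (0.01, 0.37, 42.0):
            scaled = _record(scale * rec.samples)
            assert np.array_equal(base, detect_r_peaks(scaled))

    def test_cohort_recall_precision(self, cohort20):
        matched = detected = truth_total = 0
        for rec, truth in cohort20:
            peaks = detect_r_peaks(rec)
            m, d, t = match_peaks(peaks, truth.r_peak_indices, rec.sampling_rate_hz, 50.0)
            matched += m
            detected += d
            truth_total += t
        assert matched / truth_total >= 0.99
        assert matched / detected >= 0.99


class TestFrames:
    def test_equally_spaced_peaks_midpoint_windows(self):
        rec = _record(np.arange(2048, dtype=float))
        frames = frame_beats(rec, np.asarray([512, 1024, 1536]))
        mid = frames[1]
        assert mid.samples[0] == 768  # window starts at RR midpoint
        assert mid.samples[-1] == 1279  # and ends just before the next midpoint
        assert mid.rr_prev_ms == pytest.approx(1000.0)
        assert mid.rr_next_ms == pytest.approx(1000.0)
        assert mid.r_peak_index_local == 1024 - 768

    def test_one_frame_per_peak_and_edges(self, cohort20):
        for rec, truth in cohort20[:6]:
            frames = frame_beats(rec, truth.r_peak_indices)
            assert len(frames) == len(truth.r_peak_indices)
            assert frames[0].rr_prev_ms is None
            assert frames[-1].rr_next_ms is None
            for frame in frames:
                local = frame.r_peak_index_local
                assert 0 <= local < len(frame.samples)
                assert (
                    frame.samples[local]
                    == rec.samples[frame.r_peak_index_global]
                )

    def test_single_peak_gets_rr_free_frame(self):
        rec = _record(np.zeros(2048))
        frames = frame_beats(rec, np.asarray([1000]))
        assert len(frames) == 1
        assert frames[0].rr_prev_ms is None and frames[0].rr_next_ms is None

    def test_no_peaks_no_frames(self):
        assert frame_beats(_record(np.zeros(512)), np.asarray([], dtype=int)) == []


class TestRRIntervals:
    @pytest.mark.parametrize(
        "peaks,expected",
        [([0, 512], [1000.0]), ([0, 256, 768], [500.0, 1000.0]), ([0], []), ([], [])],
    )
    def test_examples(self, peaks, expected):
        assert np.allclose(rr_intervals(np.asarray(peaks), 512.0), expected)

    def test_mean_rr_of_jitter_free_strip(self):
        rec, truth = generate_iecg(
            SyntheticSpec(seed=2, heart_rate_bpm=60, rr_jitter_fraction=0.0, age_years=16)
        )
        rr = rr_intervals(truth.r_peak_indices, rec.sampling_rate_hz)
        assert abs(float(np.mean(rr)) - 1000.0) <= 1000.0 / 512


@settings(max_examples=10, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_frames_cover_all_detected_peaks(seed):
    rec, _ = generate_iecg(
        SyntheticSpec(seed=seed, duration_s=12.0, heart_rate_bpm=100, age_years=7)
    )
    peaks = detect_r_peaks(rec)
    frames = frame_beats(rec, peaks)
    assert len(frames) == len(peaks)
    for frame, peak in zip(frames, peaks):
        start = frame.r_peak_index_global - frame.r_peak_index_local
        assert start <= peak < start + len(frame.samples)
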
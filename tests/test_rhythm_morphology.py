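"""R-peak detection, rhythm statistics, delineation, morphology."""

import numpy as np
import pytest

import cardioqt as cq
from cardioqt.lead_derivation import CHANNELS_8, derive_12_from_channels
from cardioqt.preprocess import condition
from cardioqt.rhythm_morphology import (
    ExclusionReason,
    InsufficientDataError,
    delineate_beat,
    delineate_lead,
    detect_r_peaks,
    estimate_noise_rms,
    morphology_metrics,
    rhythm_metrics,
)

FS = 500.0


def gaussian_train(r_times, duration_s, amp=1000.0, sigma=0.0129, fs=FS):
    n = int(duration_s * fs)
    t = np.arange(n) / fs
    x = np.zeros(n)
    for rt in r_times:
        x += amp * np.exp(-0.5 * ((t - rt) / sigma) ** 2)
    return x


class TestDetector:
    def test_regular_train_found_accurately(self, noiseless_recording):
        """60 bpm for ~60 s: every true R found within +-10 ms."""
        rec, truth = noiseless_recording
        peaks = detect_r_peaks(condition(rec).leads["II"], FS)
        assert abs(len(peaks) - len(truth.r_indices)) <= 1
        matched = np.array([np.min(np.abs(truth.r_indices - p)) for p in peaks])
        assert (matched <= 0.010 * FS).all()

    def test_refractory_pair_collapses_to_one(self):
        """Two identical beats 0.3 s apart yield exactly one detection."""
        r_times = [1.0, 2.0, 2.3, 3.3, 4.3]
        peaks = detect_r_peaks(gaussian_train(r_times, 6.0), FS)
        assert len(peaks) == len(r_times) - 1

    def test_flat_signal_no_peaks(self):
        assert len(detect_r_peaks(np.zeros(int(4 * FS)), FS)) == 0

    def test_short_signal_rejected(self):
        with pytest.raises(InsufficientDataError):
            detect_r_peaks(np.zeros(100), FS)

    def test_masked_peaks_discarded(self):
        x = gaussian_train([1.0, 2.0, 3.0], 5.0)
        mask = np.ones(len(x), dtype=bool)
        mask[int(1.9 * FS) : int(2.1 * FS)] = False
        peaks = detect_r_peaks(x, FS, valid_mask=mask)
        assert len(peaks) == 2
        assert not ((peaks > 1.9 * FS) & (peaks < 2.1 * FS)).any()

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_refractory_invariant_on_noise(self, seed):
        """No two accepted peaks closer than 0.4 s, whatever the input."""
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 100, int(10 * FS))
        peaks = detect_r_peaks(x, FS)
        if len(peaks) > 1:
            assert np.diff(peaks).min() >= int(0.4 * FS)


class TestRhythm:
    def test_constant_rr(self):
        peaks = np.arange(0, 10) * int(0.5 * FS)
        s = rhythm_metrics(peaks, FS)
        assert s.hr_bpm == pytest.approx(120.0)
        assert s.sdnn_ms == pytest.approx(0.0)
        assert s.n_beats == 10

    def test_two_interval_closed_form(self):
        peaks = np.array([0, int(0.8 * FS), int(1.8 * FS)])
        s = rhythm_metrics(peaks, FS)
        assert s.hr_bpm == pytest.approx(60 / 0.9, rel=1e-6)
        assert s.sdnn_ms == pytest.approx(np.sqrt((0.1**2 + 0.1**2) / 1) * 1000, rel=1e-6)

    def test_sdnn_matches_direct_formula(self, rng):
        rr = rng.uniform(0.6, 1.2, size=1000)
        peaks = np.cumsum(np.concatenate([[0.0], rr]))
        idx = np.round(peaks * FS).astype(int)
        s = rhythm_metrics(idx, FS)
        rr_q = np.diff(idx) / FS
        mean = rr_q.mean()
        oracle = np.sqrt(((rr_q - mean) ** 2).sum() / (len(rr_q) - 1)) * 1000
        assert s.sdnn_ms == pytest.approx(oracle, abs=1e-9)

    def test_too_few_peaks_gives_na(self):
        s = rhythm_metrics(np.array([100]), FS)
        assert s.hr_bpm is None and s.sdnn_ms is None and s.n_beats == 1


class TestDelineation:
    def _annotations(self, rec, truth, lead="II"):
        x = condition(derive_12_from_channels(rec)).leads[lead]
        peaks = detect_r_peaks(x, FS)
        return x, delineate_lead(x, peaks, FS)

    def test_qt_recovered_within_8ms(self, clean_session):
        rec, truth, _ = clean_session
        _, anns = self._annotations(rec, truth)
        qts = [(a.t_end - a.q_onset) / FS * 1000 for a in anns if a.valid]
        assert len(qts) >= 30
        assert abs(np.median(qts) - truth.qt_ms["II"]) <= 8.0

    def test_low_t_amplitude_excluded(self):
        """A 20 uV T wave under 10 uV noise is insufficient relative to noise."""
        beat = cq.SynthBeatParams(t_amp_mv={ch: 0.02 for ch in CHANNELS_8})
        rec, _ = cq.generate_recording(beat, cq.SynthSessionParams(seed=3))
        _, anns = self._annotations(rec, None)
        reasons = {a.exclusion_reason for a in anns if not a.valid}
        assert reasons == {ExclusionReason.LOW_T_AMPLITUDE}
        assert not any(a.valid for a in anns)

    def test_u_wave_raises_ambiguity(self):
        beat = cq.SynthBeatParams(u_amp_frac=0.3)
        rec, _ = cq.generate_recording(beat, cq.SynthSessionParams(seed=3))
        _, anns = self._annotations(rec, None)
        assert sum(a.exclusion_reason is ExclusionReason.AMBIGUOUS_MORPHOLOGY for a in anns) >= len(anns) * 0.9

    def test_window_truncation_marks_masked(self, noiseless_recording):
        rec, truth = noiseless_recording
        x = condition(rec).leads["II"]
        ann = delineate_beat(x, 10, FS, noise_rms=0.0)  # no 300 ms pre-context
        assert not ann.valid
        assert ann.exclusion_reason is ExclusionReason.MASKED_SEGMENT

    def test_time_shift_equivariance(self, noiseless_recording):
        rec, truth = noiseless_recording
        x = condition(rec).leads["II"]
        k = 37
        shifted = np.concatenate([np.zeros(k), x[:-k]])
        r = int(truth.r_indices[5])
        a = delineate_beat(x, r, FS, noise_rms=0.0)
        b = delineate_beat(shifted, r + k, FS, noise_rms=0.0)
        assert a.valid and b.valid
        for f in ("q_onset", "qrs_offset", "t_peak", "t_end"):
            assert getattr(b, f) == getattr(a, f) + k

    def test_amplitude_scale_invariance(self, noiseless_recording):
        rec, truth = noiseless_recording
        x = condition(rec).leads["II"]
        r = int(truth.r_indices[5])
        a = delineate_beat(x, r, FS, noise_rms=0.0)
        for c in (0.5, 2.0, 10.0):
            b = delineate_beat(c * x, r, FS, noise_rms=0.0)
            assert b.valid
            for f in ("q_onset", "qrs_offset", "t_peak", "t_end"):
                assert getattr(b, f) == getattr(a, f)


class TestMorphology:
    def _summary(self, beat_params, seed=4, lead="II"):
        rec, _ = cq.generate_recording(beat_params, cq.SynthSessionParams(seed=seed))
        x = condition(derive_12_from_channels(rec)).leads[lead]
        peaks = detect_r_peaks(x, FS)
        anns = delineate_lead(x, peaks, FS)
        return morphology_metrics(anns, x, FS)

    def test_st_elevation_recovered(self):
        st = {ch: 0.15 for ch in CHANNELS_8}
        m = self._summary(cq.SynthBeatParams(st_offset_mv=st))
        assert m.st_shift_mv == pytest.approx(0.15, abs=0.02)

    def test_null_st(self):
        m = self._summary(cq.SynthBeatParams())
        assert abs(m.st_shift_mv) < 0.02

    def test_t_amplitude_recovered(self):
        amp = {ch: 0.30 for ch in CHANNELS_8}
        m = self._summary(cq.SynthBeatParams(t_amp_mv=amp))
        assert m.t_amplitude_mv == pytest.approx(0.30, abs=0.03)

    def test_no_valid_beats_gives_na(self):
        m = morphology_metrics([], np.zeros(1000), FS)
        assert m.t_amplitude_mv is None and m.st_shift_mv is None and m.n_valid_beats == 0


def test_noise_rms_estimate_tracks_injected_noise():
    sess = cq.SynthSessionParams(seed=9, noise_rms_uv=20.0, baseline_wander_uv=0, mains_uv=0)
    rec, truth = cq.generate_recording(cq.SynthBeatParams(), sess)
    x = rec.leads["II"]
    est = estimate_noise_rms(x, truth.r_indices, FS)
    assert est == pytest.approx(20.0, rel=0.35)
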
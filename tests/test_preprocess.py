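"""Scaling and conditioning: LSB constant, filter contracts, masking."""

import numpy as np
import pytest

import cardioqt as cq
from cardioqt.lead_derivation import CHANNELS_8, ConfigurationError, LeadSetRecording
from cardioqt.preprocess import (
    FilterSpec,
    apply_leadoff_mask,
    condition,
    counts_to_microvolts,
    leadoff_intervals,
    lsb_microvolts,
    microvolts_to_counts,
)

FS = 500.0


def _rec(x, mask=None, name="II"):
    leads = {name: np.asarray(x, dtype=float)}
    m = None if mask is None else {name: mask}
    return LeadSetRecording(leads=leads, fs=FS, valid_mask=m)


class TestScaling:
    def test_lsb_constant(self):
        """2*2.4 V / 2^24 rounds to 0.286 uV/count."""
        assert round(lsb_microvolts(), 3) == 0.286

    def test_zero_and_unit(self):
        assert counts_to_microvolts(0) == 0.0
        assert round(float(counts_to_microvolts(1)), 3) == 0.286

    def test_full_scale_closed_form(self):
        full = float(counts_to_microvolts(2**23 - 1))
        expected = 2 * 2.4 / 2**24 * (2**23 - 1) * 1e6
        assert full == pytest.approx(expected, rel=1e-12)
        assert full == pytest.approx(2.3999997e6, rel=1e-6)

    def test_inverse_quantization_bound(self, rng):
        uv = rng.uniform(-1e5, 1e5, size=1000)
        back = counts_to_microvolts(microvolts_to_counts(uv))
        assert np.abs(back - uv).max() <= lsb_microvolts() / 2 + 1e-9

    def test_clipping_error(self):
        with pytest.raises(ValueError):
            microvolts_to_counts(np.array([2.5e6]))


class TestCondition:
    def test_dc_removed(self):
        n = int(10 * FS)
        out = condition(_rec(np.full(n, 500.0)))
        central = out.leads["II"][n // 10 : -n // 10]
        assert abs(central.mean()) < 1.0

    def test_mains_suppressed(self):
        t = np.arange(int(10 * FS)) / FS
        out = condition(_rec(100 * np.sin(2 * np.pi * 50 * t)))
        central = out.leads["II"][int(FS) : -int(FS)]
        assert np.abs(central).max() < 5.0

    def test_in_band_preserved(self):
        t = np.arange(int(10 * FS)) / FS
        out = condition(_rec(100 * np.sin(2 * np.pi * 10 * t)))
        central = out.leads["II"][int(FS) : -int(FS)]
        assert np.abs(central).max() == pytest.approx(100.0, rel=0.05)

    def test_zero_phase_no_lag(self, noiseless_recording):
        """Cross-correlation peak between clean beats and conditioned output is at lag 0."""
        rec, _ = noiseless_recording
        x = rec.leads["II"] - rec.leads["II"].mean()
        y = condition(rec).leads["II"]
        lags = np.arange(-50, 51)
        xc = [np.dot(x[50:-50], y[50 + k : len(y) - 50 + k]) for k in lags]
        assert lags[int(np.argmax(xc))] == 0

    def test_idempotent_in_band(self, noiseless_recording):
        rec, _ = noiseless_recording
        once = condition(rec)
        twice = condition(once)
        rms = lambda v: np.sqrt(np.mean(v**2))
        assert abs(rms(twice.leads["II"]) - rms(once.leads["II"])) / rms(once.leads["II"]) < 0.02

    def test_bad_cutoff_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            condition(_rec(np.zeros(int(4 * FS))), FilterSpec(lowpass_hz=400.0))

    def test_masked_samples_do_not_leak_into_valid_runs(self, rng):
        """Filtering with a masked gap equals filtering each valid run alone."""
        n = int(12 * FS)
        t = np.arange(n) / FS
        x = 200 * np.sin(2 * np.pi * 8 * t) + rng.normal(0, 10, n)
        mask = np.ones(n, dtype=bool)
        mask[int(5 * FS) : int(6 * FS)] = False
        x_corrupt = x.copy()
        x_corrupt[~mask] = 1e6  # garbage inside the masked gap
        out = condition(_rec(x_corrupt, mask))
        iso_first = condition(_rec(x[: int(5 * FS)])).leads["II"]
        np.testing.assert_allclose(out.leads["II"][: int(5 * FS)], iso_first, rtol=1e-10, atol=1e-8)

    def test_short_valid_runs_invalidated(self):
        n = int(5 * FS)
        mask = np.zeros(n, dtype=bool)
        mask[100:300] = True  # 0.4 s: below the 1 s settling minimum
        mask[1000:3000] = True  # 4 s: kept
        out = condition(_rec(np.ones(n), mask))
        assert not out.valid_mask["II"][100:300].any()
        assert out.valid_mask["II"][1000:3000].all()


class TestLeadoffMask:
    def _stream(self, n, flagged=()):
        flags = np.zeros(n, dtype=np.uint16)
        for ch, lo, hi in flagged:
            flags[lo:hi] |= 1 << CHANNELS_8.index(ch)
        mat = np.zeros((n, 8), dtype=np.int32)
        return cq.resync_stream(cq.encode_stream(mat, flags.tolist()))

    def test_no_flags_leaves_mask_unchanged(self):
        n = int(4 * FS)
        rec = LeadSetRecording(leads={ch: np.zeros(n) for ch in CHANNELS_8}, fs=FS)
        out = apply_leadoff_mask(rec, self._stream(n))
        for ch in CHANNELS_8:
            assert out.valid_mask[ch].all()

    def test_flagged_run_with_guard_bands(self):
        """2 s episode on channel I invalidates 2 s + 0.25 s guards, and the derived leads."""
        n = int(8 * FS)
        rec = LeadSetRecording(leads={ch: np.zeros(n) for ch in CHANNELS_8}, fs=FS)
        masked = apply_leadoff_mask(rec, self._stream(n, [("I", 1000, 2000)]))
        guard = int(0.25 * FS)
        assert not masked.valid_mask["I"][1000 - guard : 2000 + guard].any()
        assert masked.valid_mask["I"][: 1000 - guard - 1].all()
        assert masked.valid_mask["I"][2000 + guard + 1 :].all()
        assert masked.valid_mask["II"].all()
        rec12 = cq.derive_12_from_channels(masked)
        for name in ("III", "aVR", "aVL", "aVF"):
            assert not rec12.valid_mask[name][1000:2000].any()

    def test_episode_intervals_reported(self):
        stream = self._stream(int(4 * FS), [("V3", 500, 900)])
        assert leadoff_intervals(stream, FS) == [("V3", 1.0, 1.8)]

    def test_total_loss_all_invalid(self):
        n = int(4 * FS)
        rec = LeadSetRecording(leads={ch: np.zeros(n) for ch in CHANNELS_8}, fs=FS)
        flagged = [(ch, 0, n) for ch in CHANNELS_8]
        out = apply_leadoff_mask(rec, self._stream(n, flagged))
        for ch in CHANNELS_8:
            assert not out.valid_mask[ch].any()
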
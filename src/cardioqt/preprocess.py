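"""Raw-count scaling and signal conditioning with validity masking.

The ADC front end (ADS1298-class, Vref = 2.4 V, unity gain, 24-bit) maps one
count to 2*Vref / 2**24 volts, i.e. ~0.286 uV/count. Conditioning is the
standard ECG chain: high-pass for DC/baseline, mains notch, low-pass for
muscle/EMI — all applied forward-backward (zero phase) so fiducial latencies
are untouched. Samples flagged invalid (lead-off plus a settling guard band)
never enter filter state: each contiguous valid run is filtered in isolation
and runs too short to settle are themselves invalidated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .lead_derivation import (
    CHANNELS_8,
    DERIVED_SOURCES,
    ConfigurationError,
    LeadSetRecording,
    ShapeError,
)
from .packet_codec import RawFrameStream

#: ADC reference voltage, volts
V_REF = 2.4
#: ADC resolution, bits
ADC_BITS = 24

#: guard band invalidated on each side of a lead-off run, seconds
LEADOFF_GUARD_S = 0.25
#: shortest valid run worth filtering, seconds
MIN_RUN_S = 1.0


def lsb_microvolts() -> float:
    """Scale constant in uV/count, computed from the converter parameters."""
    return 2.0 * V_REF / 2.0**ADC_BITS * 1e6


def counts_to_microvolts(raw) -> np.ndarray:
    """U = raw * (2*Vref / 2^24), returned in microvolts."""
    return np.asarray(raw, dtype=float) * lsb_microvolts()


def microvolts_to_counts(uv) -> np.ndarray:
    """Inverse scaling with round-half-even, clipped error raised at 24-bit FS."""
    counts = np.asarray(uv, dtype=float) / lsb_microvolts()
    rounded = np.rint(counts)  # round-half-even
    full_scale = 2 ** (ADC_BITS - 1) - 1
    if np.any(np.abs(rounded) > full_scale):
        raise ValueError("amplitude exceeds 24-bit full scale")
    return rounded.astype(np.int32)


@dataclass
class FilterSpec:
    """Conditioning chain parameters (defaults follow the device pipeline)."""

    highpass_hz: float = 0.5
    notch_hz: float = 50.0
    notch_q: float = 30.0
    lowpass_hz: float = 125.0
    order: int = 4
    zero_phase: bool = True

    def validate(self, fs: float) -> None:
        nyq = fs / 2.0
        if not (0 < self.highpass_hz < self.lowpass_hz < nyq):
            raise ConfigurationError(
                f"need 0 < highpass ({self.highpass_hz}) < lowpass ({self.lowpass_hz}) < fs/2 ({nyq})"
            )
        if not (0 < self.notch_hz < nyq):
            raise ConfigurationError(f"notch_hz {self.notch_hz} outside (0, fs/2)")


def _design(spec: FilterSpec, fs: float):
    # second-order high-pass: steep enough for DC, gentle on ST-segment levels
    hp = signal.butter(2, spec.highpass_hz, btype="highpass", fs=fs, output="sos")
    lp = signal.butter(spec.order, spec.lowpass_hz, btype="lowpass", fs=fs, output="sos")
    b, a = signal.iirnotch(spec.notch_hz, spec.notch_q, fs=fs)
    notch = signal.tf2sos(b, a)
    return hp, notch, lp


def _apply_chain(x: np.ndarray, sos_chain, zero_phase: bool, fs: float) -> np.ndarray:
    # pad generously: the 0.5 Hz high-pass transient decays over ~0.5 s,
    # so reflect-pad several time constants to keep edges transient-free
    y = x
    pad = int(round(6.0 * fs))
    for sos in sos_chain:
        if zero_phase:
            y = signal.sosfiltfilt(sos, y, padlen=min(len(y) - 1, pad))
        else:
            y = signal.sosfilt(sos, y)
    return y


def _valid_runs(mask: np.ndarray):
    """Yield (start, stop) of contiguous True runs (half-open)."""
    if not mask.any():
        return
    diffs = np.flatnonzero(np.diff(mask.astype(np.int8)))
    starts = [0] if mask[0] else []
    starts += (diffs[~mask[diffs]] + 1).tolist()
    stops = (diffs[mask[diffs]] + 1).tolist()
    if mask[-1]:
        stops.append(len(mask))
    yield from zip(starts, stops)


def condition(r: LeadSetRecording, spec: FilterSpec | None = None) -> LeadSetRecording:
    """Apply the high-pass / notch / low-pass chain per contiguous valid run."""
    spec = spec or FilterSpec()
    spec.validate(r.fs)
    chain = _design(spec, r.fs)
    min_run = int(round(MIN_RUN_S * r.fs))
    out = r.copy()
    for name, x in r.leads.items():
        mask = r.valid_mask[name]
        y = np.zeros_like(x, dtype=float)
        new_mask = mask.copy()
        for start, stop in _valid_runs(mask):
            if stop - start < min_run:
                new_mask[start:stop] = False
                continue
            y[start:stop] = _apply_chain(
                np.asarray(x[start:stop], dtype=float), chain, spec.zero_phase, r.fs
            )
        out.leads[name] = y
        out.valid_mask[name] = new_mask
    return out


def apply_leadoff_mask(r: LeadSetRecording, frames: RawFrameStream) -> LeadSetRecording:
    """Invalidate samples whose packet flagged the source channel off.

    A guard band of LEADOFF_GUARD_S on each side of every lead-off run is
    also invalidated (amplifier settling after contact changes). Derived
    limb leads inherit the union of their sources' invalid samples.
    """
    off = frames.leadoff_matrix()  # (n_frames, 8) in CHANNELS_8 order
    if off.shape[0] != r.n_samples:
        raise ShapeError(f"frame count {off.shape[0]} != sample count {r.n_samples}")
    guard = int(round(LEADOFF_GUARD_S * r.fs))
    out = r.copy()

    widened = {}
    for ci, ch in enumerate(CHANNELS_8):
        bad = off[:, ci]
        if bad.any():
            # dilate each run by the guard band
            kernel = np.ones(2 * guard + 1, dtype=bool)
            bad = np.convolve(bad, kernel, mode="same") > 0
        widened[ch] = bad

    for name in out.leads:
        sources = DERIVED_SOURCES.get(name, (name,))
        bad = np.zeros(r.n_samples, dtype=bool)
        for src in sources:
            if src in widened:
                bad |= widened[src]
        out.valid_mask[name] = out.valid_mask[name] & ~bad
    return out


def leadoff_intervals(frames: RawFrameStream, fs: float) -> list[tuple[str, float, float]]:
    """Merged (channel, start_s, end_s) lead-off episodes, for pause accounting."""
    off = frames.leadoff_matrix()
    episodes = []
    for ci, ch in enumerate(CHANNELS_8):
        col = off[:, ci]
        for start, stop in _valid_runs(col):
            episodes.append((ch, start / fs, stop / fs))
    return episodes
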
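"""Ground-truth-labeled synthetic 8-channel ECG and device-stream simulation.

Beats are sums of localized Gaussian bumps (P, Q, R, S, T, optional U) so
every fiducial has a closed-form location. The conventions that make the
ground truth well defined:

* QRS onset/offset are 2.5 sigma outside the Q/S bump centers.
* The T wave is a Gaussian of width T_SIGMA_S; the steepest descending
  tangent of a Gaussian meets the baseline exactly 2 sigma past its center,
  so the T center is placed at ``q_onset + QT - 2 sigma`` and the tangent
  T-end convention reproduces the requested QT by construction.
* An optional ST plateau rises just after the J point and decays before the
  T upstroke, so it shifts the ST measurement window without biasing the
  T amplitude or the tangent intersection.

Emulated session conditions follow the device protocol: 60 s at 500 Hz,
eight transmitted channels (I, II, V1..V6), Gaussian sensor noise, slow
sinusoidal baseline wander, mains interference, and intermittent lead-off
episodes during which the channel reads zero (open circuit) and the packet
flag bit is set. All randomness is driven by the session seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .lead_derivation import CHANNELS_8, LeadSetRecording
from .packet_codec import StreamState, encode_stream
from .preprocess import microvolts_to_counts

#: T-wave Gaussian width, seconds
T_SIGMA_S = 0.040
#: QRS onset/offset sit this many sigmas outside the Q/S bump centers
EDGE_SIGMAS = 2.5

PerLead = float | dict[str, float]


def _per_lead(value: PerLead, default: float | None = None) -> dict[str, float]:
    if isinstance(value, dict):
        out = {ch: float(value.get(ch, default if default is not None else np.nan)) for ch in CHANNELS_8}
        if any(np.isnan(v) for v in out.values()):
            missing = [ch for ch, v in out.items() if np.isnan(v)]
            raise ValueError(f"per-lead map missing channels: {missing}")
        return out
    return {ch: float(value) for ch in CHANNELS_8}


# default R/T polarity-and-size profile across the transmitted channels,
# loosely shaped like a normal axis (V1 small/negative T omitted: keep all
# T waves measurable so exclusion behaviour is opt-in via parameters)
_R_PROFILE = {"I": 0.8, "II": 1.1, "V1": 0.5, "V2": 0.9, "V3": 1.3, "V4": 1.5, "V5": 1.2, "V6": 0.9}
_T_PROFILE = {"I": 0.25, "II": 0.35, "V1": 0.15, "V2": 0.4, "V3": 0.45, "V4": 0.4, "V5": 0.3, "V6": 0.25}


@dataclass
class SynthBeatParams:
    """Per-beat wave timing/amplitude parameters (ms / mV)."""

    pr_ms: float = 160.0  # P onset -> QRS onset
    p_dur_ms: float = 100.0
    qrs_ms: float = 90.0
    qt_ms: PerLead = 400.0
    t_amp_mv: PerLead = field(default_factory=lambda: dict(_T_PROFILE))
    r_amp_mv: PerLead = field(default_factory=lambda: dict(_R_PROFILE))
    st_offset_mv: PerLead = 0.0
    u_amp_frac: float = 0.0  # U amplitude as a fraction of the T amplitude

    def resolved(self):
        qt = _per_lead(self.qt_ms)
        for ch, v in qt.items():
            if v <= self.qrs_ms:
                raise ValueError(f"qt_ms ({v}) must exceed qrs_ms ({self.qrs_ms}) on {ch}")
        if self.p_dur_ms <= 0 or self.qrs_ms <= 0 or self.pr_ms <= 0:
            raise ValueError("durations must be positive")
        return (
            qt,
            _per_lead(self.t_amp_mv),
            _per_lead(self.r_amp_mv),
            _per_lead(self.st_offset_mv),
        )


@dataclass
class SynthSessionParams:
    """Session-level acquisition conditions (defaults emulate the protocol)."""

    duration_s: float = 60.0
    fs: float = 500.0
    hr_bpm: float = 60.0
    hr_jitter_sd_ms: float = 15.0
    noise_rms_uv: PerLead = 10.0
    baseline_wander_uv: float = 50.0  # amplitude of the 0.2 Hz wander
    mains_uv: float = 20.0  # amplitude of the mains sinusoid
    mains_hz: float = 50.0
    leadoff_episodes: list[tuple[str, float, float]] = field(default_factory=list)
    seed: int = 0

    def validate(self):
        if self.duration_s <= 0 or self.fs <= 0 or self.hr_bpm <= 0:
            raise ValueError("duration, fs and hr must be positive")
        for ch, start, end in self.leadoff_episodes:
            if ch not in CHANNELS_8:
                raise ValueError(f"unknown channel {ch!r} in lead-off episode")
            if not (0 <= start < end <= self.duration_s):
                raise ValueError(f"episode ({ch}, {start}, {end}) outside session")


@dataclass
class GroundTruth:
    """Exact per-beat fiducials (sample indices) and per-lead true values."""

    r_indices: np.ndarray
    q_onsets: np.ndarray
    qrs_offsets: np.ndarray
    t_ends: dict[str, np.ndarray]
    t_peaks: dict[str, np.ndarray]
    qt_ms: dict[str, float]
    rr_s: np.ndarray
    fs: float

    @property
    def qtd_ms(self) -> float:
        """True dispersion = spread of the per-lead QT targets."""
        return max(self.qt_ms.values()) - min(self.qt_ms.values())

    @property
    def rr_mean_s(self) -> float:
        return float(self.rr_s.mean()) if len(self.rr_s) else float("nan")


def _gauss(t: np.ndarray, center: float, sigma: float, amp: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((t - center) / sigma) ** 2)


def _smoothstep(t: np.ndarray, center: float, width: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(t - center) / width))


def generate_recording(
    beat: SynthBeatParams | None = None,
    sess: SynthSessionParams | None = None,
) -> tuple[LeadSetRecording, GroundTruth]:
    """Build an 8-channel recording plus its exact ground truth."""
    beat = beat or SynthBeatParams()
    sess = sess or SynthSessionParams()
    sess.validate()
    qt, t_amp, r_amp, st_off = beat.resolved()

    rng = np.random.default_rng(sess.seed)
    fs = sess.fs
    n = int(round(sess.duration_s * fs))
    t_axis = np.arange(n) / fs

    # beat schedule: RR_i = 60000/hr + N(0, jitter) ms, first R at 0.5 s
    mean_rr_s = 60.0 / sess.hr_bpm
    max_qt_s = max(qt.values()) / 1000.0
    r_times = []
    t_cursor = 0.5
    while t_cursor < sess.duration_s - max_qt_s - 0.2:
        r_times.append(t_cursor)
        rr = mean_rr_s + rng.normal(0.0, sess.hr_jitter_sd_ms / 1000.0)
        rr = max(rr, max_qt_s + 0.25)  # beats must not overlap
        t_cursor += rr
    r_times = np.asarray(r_times)
    if len(r_times) == 0:
        raise ValueError("session too short for a single beat")
    rr_s = np.diff(r_times)

    qrs_s = beat.qrs_ms / 1000.0
    sig_q = qrs_s / 10.0
    sig_r = qrs_s / 7.0
    sig_s = qrs_s / 10.0
    q_center = -0.3 * qrs_s
    s_center = +0.3 * qrs_s
    q_onset_rel = q_center - EDGE_SIGMAS * sig_q  # ~ -0.55 * qrs
    j_rel = s_center + EDGE_SIGMAS * sig_s
    sig_p = (beat.p_dur_ms / 1000.0) / 5.0
    p_center_rel = q_onset_rel - beat.pr_ms / 1000.0 + (beat.p_dur_ms / 1000.0) / 2.0

    noise = _per_lead(sess.noise_rms_uv)

    leads: dict[str, np.ndarray] = {}
    t_ends: dict[str, np.ndarray] = {}
    t_peaks: dict[str, np.ndarray] = {}
    for ch in CHANNELS_8:
        x = np.zeros(n)
        qtl_s = qt[ch] / 1000.0
        t_center_rel = q_onset_rel + qtl_s - 2.0 * T_SIGMA_S
        t_end_rel = q_onset_rel + qtl_s
        amp_r = r_amp[ch] * 1000.0  # mV -> uV
        amp_t = t_amp[ch] * 1000.0
        amp_st = st_off[ch] * 1000.0
        for rt in r_times:
            lo = max(0, int((rt - 0.45) * fs))
            hi = min(n, int((rt + qtl_s + 0.35) * fs))
            tt = t_axis[lo:hi] - rt
            w = (
                _gauss(tt, p_center_rel, sig_p, 150.0)  # P wave, fixed 0.15 mV
                + _gauss(tt, q_center, sig_q, -0.10 * amp_r)
                + _gauss(tt, 0.0, sig_r, amp_r)
                + _gauss(tt, s_center, sig_s, -0.20 * amp_r)
                + _gauss(tt, t_center_rel, T_SIGMA_S, amp_t)
            )
            if amp_st != 0.0:
                rise = _smoothstep(tt, j_rel + 0.010, 0.004)
                fall = 1.0 - _smoothstep(tt, t_center_rel - 2.5 * T_SIGMA_S, 0.006)
                w = w + amp_st * rise * fall
            if beat.u_amp_frac:
                w = w + _gauss(tt, t_end_rel + 0.15, 0.030, beat.u_amp_frac * amp_t)
            x[lo:hi] += w
        # additive disturbances (independent phase/noise per channel)
        if noise[ch] > 0:
            x += rng.normal(0.0, noise[ch], size=n)
        if sess.baseline_wander_uv > 0:
            x += sess.baseline_wander_uv * np.sin(2 * np.pi * 0.2 * t_axis + rng.uniform(0, 2 * np.pi))
        if sess.mains_uv > 0:
            x += sess.mains_uv * np.sin(2 * np.pi * sess.mains_hz * t_axis + rng.uniform(0, 2 * np.pi))
        leads[ch] = x
        t_ends[ch] = np.round((r_times + t_end_rel) * fs).astype(int)
        t_peaks[ch] = np.round((r_times + t_center_rel) * fs).astype(int)

    # open-circuit emulation: flagged samples read zero
    for ch, start, end in sess.leadoff_episodes:
        lo, hi = int(round(start * fs)), int(round(end * fs))
        leads[ch][lo:hi] = 0.0

    rec = LeadSetRecording(leads=leads, fs=fs, posture_label="synthetic")
    truth = GroundTruth(
        r_indices=np.round(r_times * fs).astype(int),
        q_onsets=np.round((r_times + q_onset_rel) * fs).astype(int),
        qrs_offsets=np.round((r_times + j_rel) * fs).astype(int),
        t_ends=t_ends,
        t_peaks=t_peaks,
        qt_ms={ch: qt[ch] for ch in CHANNELS_8},
        rr_s=rr_s,
        fs=fs,
    )
    return rec, truth


def leadoff_flag_words(sess: SynthSessionParams, n_samples: int) -> np.ndarray:
    """Per-frame 16-bit flag words for the configured lead-off episodes."""
    flags = np.zeros(n_samples, dtype=np.uint16)
    for ch, start, end in sess.leadoff_episodes:
        bit = CHANNELS_8.index(ch)
        lo, hi = int(round(start * sess.fs)), int(round(end * sess.fs))
        flags[lo:hi] |= 1 << bit
    return flags


def stream_as_packets(r: LeadSetRecording, sess: SynthSessionParams) -> bytes:
    """Serialize an 8-channel recording as the device's packet stream."""
    if tuple(r.channel_names) != CHANNELS_8:
        raise ValueError(f"need the 8 transmitted channels in order {CHANNELS_8}")
    mat_uv = np.column_stack([r.leads[ch] for ch in CHANNELS_8])
    counts = microvolts_to_counts(mat_uv)
    flags = leadoff_flag_words(sess, r.n_samples)
    return encode_stream(counts, flags.tolist(), StreamState())
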
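"""R-peak detection, rhythm statistics, and beat delineation.

Detection follows the Pan–Tompkins pattern: band-pass to the QRS band,
squaring, moving-window integration, then block-adaptive thresholding of the
integrated energy. A refractory rule keeps only the strongest candidate when
two land closer than REFRACTORY_S apart (exactly REFRACTORY_S apart is
allowed). Detection runs offline, so the band-pass is zero-phase and the
threshold may look at the whole record.

Delineation measures, per beat: Q onset and QRS offset (J point) by a
relative slope-threshold search around R, T peak as the largest baseline
deviation in a post-J window, and T end by the tangent method — the steepest
post-peak tangent extrapolated to the isoelectric (PQ) baseline. Beats are
excluded, with a reason, when the T wave is too small relative to noise,
when morphology is ambiguous (U-wave suspicion or biphasic T), or when the
tangent never returns to baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import signal

#: refractory interval between accepted R peaks, seconds
REFRACTORY_S = 0.4
#: moving-window integration length, seconds
MWI_S = 0.15
#: QRS band for the detection band-pass, Hz
QRS_BAND = (5.0, 25.0)

# --- delineation windows and thresholds (see docs/methods.md) ---
Q_SEARCH_S = 0.12  # backward search span for Q onset
J_SEARCH_S = 0.12  # forward search span for QRS offset
SLOPE_FRAC = 0.03  # slope threshold relative to peak QRS slope
SLOPE_RUN_S = 0.006  # slope must stay low this long to call an onset/offset
T_WIN_AFTER_J = (0.08, 0.40)  # T-peak search window relative to J, seconds
T_FLOOR_UV = 50.0  # absolute T-amplitude floor, microvolts
T_NOISE_MULT = 3.0  # T must exceed this multiple of noise RMS
TANGENT_MAX_S = 0.25  # tangent must cross baseline within this of T peak
U_WINDOW_S = 0.20  # U-wave search window after tentative T end
U_FRAC = 0.25  # same-sign deflection fraction that raises U suspicion
PQ_BASELINE_S = 0.040  # PQ window (ending at Q onset) used as baseline
PRE_R_S = 0.3  # context required before R
POST_R_S = 0.7  # context required after R
ST_WINDOW_S = (0.060, 0.080)  # ST measurement window relative to J
P_SEARCH_S = (0.250, 0.020)  # P search window before Q onset
P_EDGE_FRAC = 0.05  # P bounds at this fraction of P peak amplitude
EDGE_SMOOTH_S = 0.018  # Savitzky-Golay window for QRS edge slopes (narrow waves)
T_SMOOTH_S = 0.050  # Savitzky-Golay window for the T wave (broad, noise-limited)


class InsufficientDataError(ValueError):
    pass


class ExclusionReason(Enum):
    NONE = "none"
    LOW_T_AMPLITUDE = "low_t_amplitude"
    AMBIGUOUS_MORPHOLOGY = "ambiguous_morphology"
    TEND_UNDETECTABLE = "tend_undetectable"
    MASKED_SEGMENT = "masked_segment"


@dataclass
class BeatAnnotation:
    """Per-beat fiducials (0-based sample indices) and validity."""

    r_index: int
    q_onset: int | None = None
    qrs_offset: int | None = None
    t_peak: int | None = None
    t_end: int | None = None
    p_onset: int | None = None
    p_offset: int | None = None
    rr_prev_s: float | None = None
    valid: bool = False
    exclusion_reason: ExclusionReason = ExclusionReason.NONE


@dataclass
class RhythmSummary:
    rr_intervals_s: np.ndarray
    hr_bpm: float | None
    sdnn_ms: float | None
    n_beats: int


@dataclass
class MorphologySummary:
    """Per-lead medians over valid beats; None where not measurable."""

    p_duration_ms: float | None
    qrs_width_ms: float | None
    t_amplitude_mv: float | None
    st_shift_mv: float | None
    n_valid_beats: int = 0


def _bandpass_qrs(x: np.ndarray, fs: float) -> np.ndarray:
    sos = signal.butter(2, QRS_BAND, btype="bandpass", fs=fs, output="sos")
    padlen = min(len(x) - 1, 300)
    return signal.sosfiltfilt(sos, x, padlen=padlen)


def detect_r_peaks(lead: np.ndarray, fs: float, valid_mask: np.ndarray | None = None) -> np.ndarray:
    """Sorted R-peak sample indices on a conditioned lead.

    Candidates are local maxima of the integrated QRS energy above a
    block-adaptive threshold, refined to the largest band-passed deflection
    nearby, then thinned so no two accepted peaks are closer than
    REFRACTORY_S (the stronger candidate wins). Peaks falling in masked
    samples are discarded.
    """
    x = np.asarray(lead, dtype=float)
    if len(x) < 2 * fs:
        raise InsufficientDataError("need at least 2 s of signal")
    bp = _bandpass_qrs(x, fs)
    sq = bp * bp
    win = max(1, int(round(MWI_S * fs)))
    integ = np.convolve(sq, np.ones(win) / win, mode="same")

    gmax = integ.max()
    if gmax <= 0:
        return np.array([], dtype=int)

    # block-adaptive threshold: per 10-s block, a fraction of the local
    # maximum, floored by a fraction of the global maximum
    block = int(round(10 * fs))
    thr = np.empty_like(integ)
    for start in range(0, len(integ), block):
        seg = integ[start : start + block]
        thr[start : start + block] = max(0.2 * seg.max(), 0.05 * gmax)

    min_dist = max(1, int(round(0.2 * fs)))
    cand, props = signal.find_peaks(integ, height=1e-12, distance=min_dist)
    cand = cand[integ[cand] >= thr[cand]]
    if len(cand) == 0:
        return np.array([], dtype=int)

    # refine each candidate to the strongest |band-passed| sample nearby
    half = int(round(0.1 * fs))
    refined = []
    for c in cand:
        lo, hi = max(0, c - half), min(len(x), c + half + 1)
        refined.append(lo + int(np.argmax(np.abs(bp[lo:hi]))))
    refined = np.asarray(refined)

    # refractory thinning: strongest-first greedy, spacing >= REFRACTORY_S kept
    refractory = int(round(REFRACTORY_S * fs))
    order = np.argsort(integ[cand])[::-1]
    accepted: list[int] = []
    for k in order:
        r = refined[k]
        if all(abs(r - a) >= refractory for a in accepted):
            accepted.append(int(r))
    peaks = np.unique(accepted)

    if valid_mask is not None:
        peaks = peaks[valid_mask[peaks]]
    return peaks.astype(int)


def rhythm_metrics(r_peaks: np.ndarray, fs: float) -> RhythmSummary:
    """RR intervals, HR = 60/mean(RR), SDNN = sample SD of RR in ms."""
    r_peaks = np.asarray(r_peaks)
    n = len(r_peaks)
    if n < 2:
        return RhythmSummary(np.array([]), None, None, n)
    rr = np.diff(r_peaks) / fs
    hr = 60.0 / rr.mean()
    sdnn = float(np.std(rr, ddof=1) * 1000.0) if n >= 3 else None
    return RhythmSummary(rr, float(hr), sdnn, n)


def estimate_noise_rms(lead: np.ndarray, r_peaks: np.ndarray, fs: float) -> float:
    """Noise RMS from PQ-segment residuals: 1.4826 * MAD about each window mean."""
    resid = []
    w = int(round(PQ_BASELINE_S * fs))
    off = int(round(0.06 * fs))  # PQ region roughly 60 ms before R
    for r in np.asarray(r_peaks):
        lo, hi = r - off - w, r - off
        if lo < 0:
            continue
        seg = np.asarray(lead[lo:hi], dtype=float)
        resid.extend(seg - seg.mean())
    if not resid:
        return 0.0
    resid = np.asarray(resid)
    return float(1.4826 * np.median(np.abs(resid - np.median(resid))))


def _slope_edge(d: np.ndarray, r: int, span: int, thr: float, run: int, direction: int) -> int | None:
    """March from r in *direction* until |slope| stays below thr for `run` samples."""
    low = 0
    i = r + direction
    end = r + direction * span
    while (i - end) * direction <= 0 and 0 <= i < len(d):
        if abs(d[i]) < thr:
            low += 1
            if low >= run:
                return i - direction * (run - 1)
        else:
            low = 0
        i += direction
    return None


def delineate_beat(
    lead: np.ndarray,
    r_index: int,
    fs: float,
    noise_rms: float,
    valid_mask: np.ndarray | None = None,
    rr_prev_s: float | None = None,
) -> BeatAnnotation:
    """Annotate one beat; sets an exclusion reason instead of raising."""
    x = np.asarray(lead, dtype=float)
    ann = BeatAnnotation(r_index=int(r_index), rr_prev_s=rr_prev_s)
    pre = int(round(PRE_R_S * fs))
    post = int(round(POST_R_S * fs))
    if r_index - pre < 0 or r_index + post > len(x):
        ann.exclusion_reason = ExclusionReason.MASKED_SEGMENT
        return ann
    if valid_mask is not None and not valid_mask[r_index - pre : r_index + post].all():
        ann.exclusion_reason = ExclusionReason.MASKED_SEGMENT
        return ann

    # work on the beat window; two smoothing scales — narrow for QRS edges,
    # broad for the T wave, whose width permits (and noise demands) it
    lo, hi = r_index - pre, r_index + post
    w = x[lo:hi]
    win_e = max(5, int(round(EDGE_SMOOTH_S * fs)) | 1)  # odd lengths
    win_t = max(7, int(round(T_SMOOTH_S * fs)) | 1)
    dw = signal.savgol_filter(w, win_e, 3, deriv=1)
    ws = signal.savgol_filter(w, win_t, 3)
    dt = signal.savgol_filter(w, win_t, 3, deriv=1)
    rw = r_index - lo

    span_q = int(round(Q_SEARCH_S * fs))
    span_j = int(round(J_SEARCH_S * fs))
    run = max(2, int(round(SLOPE_RUN_S * fs)))
    qrs_slope = np.abs(dw[max(0, rw - span_q) : rw + span_j]).max()
    thr = SLOPE_FRAC * qrs_slope

    q_onset = _slope_edge(dw, rw, span_q, thr, run, direction=-1)
    j_point = _slope_edge(dw, rw, span_j, thr, run, direction=+1)
    if q_onset is None or j_point is None or not (q_onset < rw < j_point):
        ann.exclusion_reason = ExclusionReason.AMBIGUOUS_MORPHOLOGY
        return ann
    ann.q_onset, ann.qrs_offset = int(q_onset + lo), int(j_point + lo)

    pq = int(round(PQ_BASELINE_S * fs))
    baseline = float(w[max(0, q_onset - pq) : q_onset].mean())

    t_lo = j_point + int(round(T_WIN_AFTER_J[0] * fs))
    t_hi = min(len(w), j_point + int(round(T_WIN_AFTER_J[1] * fs)))
    if t_hi - t_lo < 3:
        ann.exclusion_reason = ExclusionReason.MASKED_SEGMENT
        return ann
    dev = ws[t_lo:t_hi] - baseline
    t_peak = t_lo + int(np.argmax(np.abs(dev)))
    t_amp = float(ws[t_peak] - baseline)
    ann.t_peak = int(t_peak + lo)

    amp_floor = max(T_FLOOR_UV, T_NOISE_MULT * noise_rms)
    if abs(t_amp) < amp_floor:
        ann.exclusion_reason = ExclusionReason.LOW_T_AMPLITUDE
        return ann

    # biphasic T: both polarities individually large enough to be a T wave
    if dev.max() >= amp_floor and (-dev).max() >= amp_floor:
        ann.exclusion_reason = ExclusionReason.AMBIGUOUS_MORPHOLOGY
        return ann

    t_end = _tangent_t_end(ws, dt, t_peak, baseline, t_amp, fs)
    if t_end is None:
        ann.exclusion_reason = ExclusionReason.TEND_UNDETECTABLE
        return ann
    ann.t_end = int(t_end + lo)

    # U-wave suspicion: same-sign deflection soon after the tentative T end
    u_hi = min(len(w), t_end + int(round(U_WINDOW_S * fs)))
    if u_hi > t_end + 1:
        u_dev = np.sign(t_amp) * (ws[t_end + 1 : u_hi] - baseline)
        if u_dev.max(initial=-np.inf) >= U_FRAC * abs(t_amp):
            ann.exclusion_reason = ExclusionReason.AMBIGUOUS_MORPHOLOGY
            return ann

    _annotate_p_wave(ann, ws, lo, fs, baseline, noise_rms, q_onset)
    ann.valid = True
    return ann


def _tangent_t_end(ws: np.ndarray, dw: np.ndarray, t_peak: int, baseline: float, t_amp: float, fs: float) -> int | None:
    """Steepest post-peak tangent extrapolated to the baseline (window coords)."""
    lim = min(len(ws) - 1, t_peak + int(round(TANGENT_MAX_S * fs)))
    if lim <= t_peak + 1:
        return None
    seg = dw[t_peak : lim + 1]
    # descending limb slope sign is opposite to the T polarity
    signed = -np.sign(t_amp) * seg
    m = int(np.argmax(signed))
    slope = seg[m]
    if signed[m] <= 0:
        return None
    idx = t_peak + m
    t_end = idx + (baseline - ws[idx]) / slope
    if not (t_peak < t_end <= t_peak + TANGENT_MAX_S * fs):
        return None
    t_end = int(round(t_end))
    return min(t_end, len(ws) - 1)


def _annotate_p_wave(
    ann: BeatAnnotation, ws: np.ndarray, offset: int, fs: float,
    baseline: float, noise_rms: float, q_onset_w: int,
) -> None:
    lo = q_onset_w - int(round(P_SEARCH_S[0] * fs))
    hi = q_onset_w - int(round(P_SEARCH_S[1] * fs))
    if lo < 0 or hi - lo < 3:
        return
    dev = ws[lo:hi] - baseline
    p_peak = lo + int(np.argmax(np.abs(dev)))
    p_amp = ws[p_peak] - baseline
    if abs(p_amp) < max(25.0, 2.0 * noise_rms):
        return
    edge = P_EDGE_FRAC * abs(p_amp)
    below = np.abs(ws[lo:hi] - baseline) < edge
    k = p_peak - lo
    on = np.flatnonzero(below[:k])
    off = np.flatnonzero(below[k:])
    if len(on) == 0 or len(off) == 0:
        return
    ann.p_onset = offset + lo + int(on[-1])
    ann.p_offset = offset + lo + k + int(off[0])


def delineate_lead(
    lead: np.ndarray,
    r_peaks: np.ndarray,
    fs: float,
    valid_mask: np.ndarray | None = None,
    noise_rms: float | None = None,
) -> list[BeatAnnotation]:
    """Delineate every detected beat on one lead."""
    if noise_rms is None:
        noise_rms = estimate_noise_rms(lead, r_peaks, fs)
    out = []
    prev = None
    for r in np.asarray(r_peaks, dtype=int):
        rr = (r - prev) / fs if prev is not None else None
        out.append(delineate_beat(lead, r, fs, noise_rms, valid_mask=valid_mask, rr_prev_s=rr))
        prev = r
    return out


def morphology_metrics(beats: list[BeatAnnotation], lead: np.ndarray, fs: float) -> MorphologySummary:
    """Per-lead medians of P duration, QRS width, T amplitude, ST shift."""
    x = np.asarray(lead, dtype=float)
    p_dur, qrs_w, t_amp, st = [], [], [], []
    w = int(round(PQ_BASELINE_S * fs))
    st_lo, st_hi = (int(round(s * fs)) for s in ST_WINDOW_S)
    n_valid = 0
    for b in beats:
        if not b.valid or b.q_onset is None or b.qrs_offset is None:
            continue
        n_valid += 1
        baseline = float(x[max(0, b.q_onset - w) : b.q_onset].mean())
        qrs_w.append((b.qrs_offset - b.q_onset) / fs * 1000.0)
        if b.t_peak is not None:
            t_amp.append((x[b.t_peak] - baseline) / 1000.0)  # uV -> mV
        j = b.qrs_offset
        if j + st_hi <= len(x):
            st.append((float(x[j + st_lo : j + st_hi].mean()) - baseline) / 1000.0)
        if b.p_onset is not None and b.p_offset is not None:
            p_dur.append((b.p_offset - b.p_onset) / fs * 1000.0)

    med = lambda v: float(np.median(v)) if v else None
    return MorphologySummary(
        p_duration_ms=med(p_dur),
        qrs_width_ms=med(qrs_w),
        t_amplitude_mv=med(t_amp),
        st_shift_mv=med(st),
        n_valid_beats=n_valid,
    )
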
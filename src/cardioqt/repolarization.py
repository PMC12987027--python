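"""Ventricular repolarization analysis: QT, Bazett QTc, QT dispersion.

QT is measured per cardiac cycle as Q onset -> T end. Per lead, robust
outlier filtering (MAD, with IQR fallback when the MAD collapses) is applied
to the per-beat QT values and the median of the retained values is the
lead's QT estimate. A lead enters the dispersion calculation only when its
retained cycle count is sufficient (N >= 30 valid cycles, or at least half
of all cycles in the analyzed fragment). QT dispersion is max - min of the
eligible leads' estimates and is reported as NA when fewer than K = 6 of the
considered leads (I, II, V1..V6) are eligible. The recording-level QT is the
lead II estimate; QTc = QT / sqrt(mean RR) per Bazett, using the fragment's
mean RR. Postures are never pooled: one summary per posture recording.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .lead_derivation import LeadSetRecording
from .rhythm_morphology import BeatAnnotation, rhythm_metrics

QTD_LEADS_DEFAULT = ("I", "II", "V1", "V2", "V3", "V4", "V5", "V6")


@dataclass
class RepolConfig:
    min_valid_cycles: int = 30
    min_valid_fraction: float = 0.5
    min_eligible_leads: int = 6
    outlier_method: str = "mad"  # "mad" | "iqr"
    mad_k: float = 3.0
    iqr_k: float = 1.5
    leads_considered: tuple[str, ...] = QTD_LEADS_DEFAULT

    def __post_init__(self):
        if self.min_valid_cycles <= 0 or self.min_eligible_leads <= 0:
            raise ValueError("thresholds must be positive")
        if not 0 < self.min_valid_fraction <= 1:
            raise ValueError("min_valid_fraction must be in (0, 1]")
        if self.outlier_method not in ("mad", "iqr"):
            raise ValueError(f"unknown outlier_method {self.outlier_method!r}")


@dataclass
class LeadQTEstimate:
    qt_values_ms: list[float]
    n_valid: int
    n_total: int
    qt_median_ms: float | None
    eligible: bool
    ineligibility_reason: str | None  # None | "insufficient_cycles" | "no_beats"


@dataclass
class RepolSummary:
    per_lead: dict[str, LeadQTEstimate]
    qt_ms: float | None
    qtc_ms: float | None
    qtd_ms: float | None
    rr_mean_s: float | None
    n_eligible_leads: int = 0


def beat_qt(b: BeatAnnotation, fs: float) -> float | None:
    """(t_end - q_onset)/fs in ms; absent (None) for excluded beats."""
    if not b.valid or b.q_onset is None or b.t_end is None:
        return None
    return (b.t_end - b.q_onset) / fs * 1000.0


def _iqr_filter(values: np.ndarray, k: float) -> np.ndarray:
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    return (values >= q1 - k * iqr) & (values <= q3 + k * iqr)


def robust_filter(qt_values, cfg: RepolConfig | None = None) -> list[float]:
    """Drop outliers by the MAD rule (IQR fallback when MAD = 0); order kept."""
    cfg = cfg or RepolConfig()
    values = np.asarray(list(qt_values), dtype=float)
    if len(values) == 0:
        return []
    if cfg.outlier_method == "mad":
        med = np.median(values)
        mad = np.median(np.abs(values - med))
        if mad > 0:
            keep = np.abs(values - med) <= cfg.mad_k * 1.4826 * mad
        else:
            keep = _iqr_filter(values, cfg.iqr_k)
    else:
        keep = _iqr_filter(values, cfg.iqr_k)
    return values[keep].tolist()


def lead_qt_estimate(qt_values, n_total_cycles: int, cfg: RepolConfig | None = None) -> LeadQTEstimate:
    """Robust per-lead QT median with the eligibility verdict.

    Eligible when the retained count reaches min_valid_cycles, or at least
    min_valid_fraction of all cycles in the fragment (disjunctive rule).
    """
    cfg = cfg or RepolConfig()
    if n_total_cycles < 1:
        return LeadQTEstimate([], 0, max(0, n_total_cycles), None, False, "no_beats")
    retained = robust_filter(qt_values, cfg)
    n = len(retained)
    eligible = n > 0 and (
        n >= cfg.min_valid_cycles or n >= cfg.min_valid_fraction * n_total_cycles
    )
    if eligible:
        return LeadQTEstimate(retained, n, n_total_cycles, float(np.median(retained)), True, None)
    return LeadQTEstimate(retained, n, n_total_cycles, None, False, "insufficient_cycles")


def qt_dispersion(per_lead: dict[str, LeadQTEstimate], cfg: RepolConfig | None = None) -> float | None:
    """max - min of eligible leads' QT medians; NA below the K-lead minimum."""
    cfg = cfg or RepolConfig()
    medians = [
        est.qt_median_ms
        for name, est in per_lead.items()
        if name in cfg.leads_considered and est.eligible and est.qt_median_ms is not None
    ]
    if len(medians) < cfg.min_eligible_leads:
        return None
    return float(max(medians) - min(medians))


def bazett_qtc(qt_ms: float, rr_mean_s: float) -> float:
    """QTc = QT / sqrt(RR), QT in ms, RR in seconds."""
    if rr_mean_s <= 0:
        raise ValueError("rr_mean_s must be positive")
    return qt_ms / math.sqrt(rr_mean_s)


def analyze_repolarization(
    r: LeadSetRecording,
    beats: dict[str, list[BeatAnnotation]],
    cfg: RepolConfig | None = None,
) -> RepolSummary:
    """Full per-recording repolarization pipeline over the considered leads."""
    cfg = cfg or RepolConfig()
    missing = [ld for ld in cfg.leads_considered if ld not in r.leads]
    if missing:
        raise ValueError(f"leads_considered not in recording: {missing}")

    per_lead: dict[str, LeadQTEstimate] = {}
    for name in cfg.leads_considered:
        anns = beats.get(name, [])
        qts = [q for q in (beat_qt(b, r.fs) for b in anns) if q is not None]
        per_lead[name] = lead_qt_estimate(qts, len(anns), cfg)

    qtd = qt_dispersion(per_lead, cfg)
    n_eligible = sum(est.eligible for est in per_lead.values())

    qt_ms = per_lead["II"].qt_median_ms if "II" in per_lead else None
    rr_mean = None
    lead_ii = beats.get("II", [])
    r_idx = np.array([b.r_index for b in lead_ii], dtype=int)
    if len(r_idx) >= 2:
        rhythm = rhythm_metrics(r_idx, r.fs)
        if rhythm.hr_bpm is not None:
            rr_mean = float(rhythm.rr_intervals_s.mean())
    qtc = bazett_qtc(qt_ms, rr_mean) if (qt_ms is not None and rr_mean is not None and rr_mean > 0) else None

    return RepolSummary(
        per_lead=per_lead,
        qt_ms=qt_ms,
        qtc_ms=qtc,
        qtd_ms=qtd,
        rr_mean_s=rr_mean,
        n_eligible_leads=n_eligible,
    )
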
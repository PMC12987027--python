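"""Feature-vector assembly, reference-range flagging, and T-end agreement.

The feature vector gathers rhythm (HR, SDNN), morphology (P duration, QRS
width, T amplitude, ST shift — lead II medians) and repolarization (QT, QTc,
QTd) metrics for one posture recording. Values are flagged against shipped
reference ranges (normal-limit conventions common in adult resting ECG);
upstream NA values propagate as `not_assessed`, never imputed. The expert
agreement operation summarizes beat-paired T-end placement differences
(expert minus automatic) as mean, MAE, and sample SD.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, field
from enum import Enum

import numpy as np

from .lead_derivation import ConfigurationError
from .repolarization import RepolSummary
from .rhythm_morphology import MorphologySummary, RhythmSummary


class Flag(Enum):
    IN_RANGE = "in_range"
    OUT_LOW = "out_low"
    OUT_HIGH = "out_high"
    NOT_ASSESSED = "not_assessed"


@dataclass(frozen=True)
class ReferenceRange:
    """[lower, upper) by default; inclusivity overridable per bound."""

    parameter: str
    lower: float | None = None
    upper: float | None = None
    lower_inclusive: bool = True
    upper_inclusive: bool = False
    sex_dependent: dict[str, "ReferenceRange"] | None = None
    deviation_direction: str = ""

    def __post_init__(self):
        if self.lower is not None and self.upper is not None and self.lower > self.upper:
            raise ValueError("lower bound exceeds upper bound")

    def classify(self, value: float | None) -> Flag:
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return Flag.NOT_ASSESSED
        if self.lower is not None:
            below = value < self.lower if self.lower_inclusive else value <= self.lower
            if below:
                return Flag.OUT_LOW
        if self.upper is not None:
            above = value >= self.upper if not self.upper_inclusive else value > self.upper
            if above:
                return Flag.OUT_HIGH
        return Flag.IN_RANGE


def default_reference_ranges() -> dict[str, ReferenceRange]:
    """Adult resting-ECG normal limits used for screening flags."""
    qtc_male = ReferenceRange("qtc_ms", upper=450.0, deviation_direction="prolongation")
    qtc_female = ReferenceRange("qtc_ms", upper=470.0, deviation_direction="prolongation")
    return {
        "rr_mean_s": ReferenceRange(
            "rr_mean_s", lower=0.6, upper=1.0, upper_inclusive=True,
            deviation_direction="tachy-/bradycardia",
        ),
        "hr_bpm": ReferenceRange(
            "hr_bpm", lower=60.0, upper=100.0, upper_inclusive=True,
            deviation_direction="tachy-/bradycardia",
        ),
        "sdnn_ms": ReferenceRange(
            "sdnn_ms", lower=50.0, lower_inclusive=False, deviation_direction="decrease",
        ),
        "qt_ms": ReferenceRange(
            "qt_ms", lower=350.0, upper=440.0, upper_inclusive=True,
            deviation_direction="prolongation",
        ),
        # sex-specific upper limits; unknown sex falls back to the stricter bound
        "qtc_ms": ReferenceRange(
            "qtc_ms", upper=450.0,
            sex_dependent={"male": qtc_male, "female": qtc_female},
            deviation_direction="prolongation",
        ),
        "qtd_ms": ReferenceRange("qtd_ms", upper=50.0, deviation_direction="increase"),
        "t_amplitude_mv": ReferenceRange(
            "t_amplitude_mv", lower=0.1, upper=0.5, upper_inclusive=True,
            deviation_direction="reduction",
        ),
        "st_shift_mv": ReferenceRange(
            "st_shift_mv", lower=-0.1, upper=0.1, upper_inclusive=True,
            deviation_direction="depression",
        ),
    }


@dataclass
class FeatureVector:
    """Rhythm / morphology / repolarization metrics for one posture recording."""

    recording_id: str = ""
    posture_label: str = ""
    qt_ms: float | None = None
    qtc_ms: float | None = None
    qtd_ms: float | None = None
    t_amplitude_mv: float | None = None
    st_shift_mv: float | None = None
    hr_bpm: float | None = None
    sdnn_ms: float | None = None
    p_duration_ms: float | None = None
    qrs_width_ms: float | None = None
    rr_mean_s: float | None = None

    #: metric fields in documented export order
    METRICS = (
        "qtc_ms", "qtd_ms", "t_amplitude_mv", "st_shift_mv", "hr_bpm",
        "sdnn_ms", "qt_ms", "p_duration_ms", "qrs_width_ms", "rr_mean_s",
    )

    def to_dict(self) -> dict:
        return {
            "recording_id": self.recording_id,
            "posture_label": self.posture_label,
            **{k: getattr(self, k) for k in self.METRICS},
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureVector":
        return cls(**{k: d.get(k) for k in ("recording_id", "posture_label") + cls.METRICS})


@dataclass
class TendAgreement:
    deltas_ms: np.ndarray
    mean_ms: float
    mae_ms: float
    sd_ms: float
    n_beats: int


def build_feature_vector(
    rhythm: RhythmSummary,
    morph: MorphologySummary,
    repol: RepolSummary,
    recording_id: str = "",
    posture_label: str = "",
) -> FeatureVector:
    """Combine one posture recording's summaries; NA propagates as None."""
    return FeatureVector(
        recording_id=recording_id,
        posture_label=posture_label,
        qt_ms=repol.qt_ms,
        qtc_ms=repol.qtc_ms,
        qtd_ms=repol.qtd_ms,
        t_amplitude_mv=morph.t_amplitude_mv,
        st_shift_mv=morph.st_shift_mv,
        hr_bpm=rhythm.hr_bpm,
        sdnn_ms=rhythm.sdnn_ms,
        p_duration_ms=morph.p_duration_ms,
        qrs_width_ms=morph.qrs_width_ms,
        rr_mean_s=repol.rr_mean_s,
    )


def flag_against_reference(
    v: FeatureVector,
    ranges: dict[str, ReferenceRange] | None = None,
    sex: str | None = None,
) -> dict[str, Flag]:
    """Threshold every ranged parameter; NA -> not_assessed."""
    ranges = ranges if ranges is not None else default_reference_ranges()
    unknown = [k for k in ranges if k not in FeatureVector.METRICS]
    if unknown:
        raise ConfigurationError(f"reference ranges for unknown parameters: {unknown}")
    out: dict[str, Flag] = {}
    for name, rng in ranges.items():
        if rng.sex_dependent and sex is not None:
            key = sex.lower()
            if key not in rng.sex_dependent:
                raise ConfigurationError(f"no {name} bound for sex {sex!r}")
            rng = rng.sex_dependent[key]
        out[name] = rng.classify(getattr(v, name))
    return out


def tend_agreement(expert_ms, auto_ms) -> TendAgreement:
    """Beat-paired T-end differences, expert - automatic, in ms."""
    expert = np.asarray(expert_ms, dtype=float)
    auto = np.asarray(auto_ms, dtype=float)
    if expert.shape != auto.shape or expert.ndim != 1:
        raise ValueError("expert and automatic positions must be equal-length 1-D sequences")
    deltas = expert - auto
    n = len(deltas)
    if n == 0:
        raise ValueError("no paired beats")
    sd = float(np.std(deltas, ddof=1)) if n > 1 else 0.0
    return TendAgreement(
        deltas_ms=deltas,
        mean_ms=float(deltas.mean()),
        mae_ms=float(np.abs(deltas).mean()),
        sd_ms=sd,
        n_beats=n,
    )
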
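"""Standard 12-lead construction from electrode potentials or device channels.

The device transmits eight channels (I, II, V1..V6); the remaining four
leads are linear combinations of I and II:

    III = II - I
    aVR = -(I + II)/2
    aVL = I - II/2
    aVF = II - I/2

These identities follow from the classical Einthoven/Goldberger definitions
with the Wilson central terminal WCT = (RA + LA + LL)/3 as the unipolar
reference. All signals are in microvolts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

LEADS_12 = ("I", "II", "III", "aVR", "aVL", "aVF", "V1", "V2", "V3", "V4", "V5", "V6")
CHANNELS_8 = ("I", "II", "V1", "V2", "V3", "V4", "V5", "V6")
PRECORDIAL = ("V1", "V2", "V3", "V4", "V5", "V6")

#: source channels each derived limb lead depends on (for mask propagation)
DERIVED_SOURCES = {"III": ("I", "II"), "aVR": ("I", "II"), "aVL": ("I", "II"), "aVF": ("I", "II")}


class ShapeError(ValueError):
    pass


class ConfigurationError(ValueError):
    pass


@dataclass
class ElectrodePotentials:
    """Electrode-site potential time series, microvolts.

    RL is the driven/reference electrode: it appears in no lead formula and
    is accepted only for completeness.
    """

    RA: np.ndarray
    LA: np.ndarray
    LL: np.ndarray
    V1e: np.ndarray
    V2e: np.ndarray
    V3e: np.ndarray
    V4e: np.ndarray
    V5e: np.ndarray
    V6e: np.ndarray
    RL: np.ndarray | None = None
    fs: float = 500.0

    def __post_init__(self):
        series = [self.RA, self.LA, self.LL] + [getattr(self, f"V{i}e") for i in range(1, 7)]
        lengths = {len(np.asarray(s)) for s in series}
        if len(lengths) != 1:
            raise ShapeError(f"electrode series lengths differ: {sorted(lengths)}")


@dataclass
class LeadSetRecording:
    """Time-aligned multichannel ECG at fixed fs with per-sample validity.

    `leads` maps channel name -> 1-D float array (microvolts); every channel
    shares the same length. `valid_mask` has the same keys/shapes; False
    marks samples excluded from analysis (lead-off, guard bands, edges).
    """

    leads: dict[str, np.ndarray]
    fs: float = 500.0
    valid_mask: dict[str, np.ndarray] | None = None
    posture_label: str = ""

    def __post_init__(self):
        if self.fs <= 0:
            raise ConfigurationError("fs must be positive")
        lengths = {len(v) for v in self.leads.values()}
        if len(lengths) > 1:
            raise ShapeError(f"channel lengths differ: {sorted(lengths)}")
        if self.valid_mask is None:
            self.valid_mask = {k: np.ones(len(v), dtype=bool) for k, v in self.leads.items()}
        else:
            for k, v in self.leads.items():
                if k not in self.valid_mask or len(self.valid_mask[k]) != len(v):
                    raise ShapeError(f"valid_mask shape mismatch for lead {k}")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.leads.values())))

    @property
    def channel_names(self) -> tuple[str, ...]:
        return tuple(self.leads)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy(self) -> "LeadSetRecording":
        return LeadSetRecording(
            leads={k: v.copy() for k, v in self.leads.items()},
            fs=self.fs,
            valid_mask={k: v.copy() for k, v in self.valid_mask.items()},
            posture_label=self.posture_label,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({k: self.leads[k] for k in self.leads})

    def to_csv(self, path) -> None:
        """Write a channel-per-column CSV; fs and units in a comment header."""
        with open(path, "w") as fh:
            fh.write(f"# fs_hz={self.fs} units=uV posture={self.posture_label}\n")
            self.to_dataframe().to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "LeadSetRecording":
        fs = 500.0
        posture = ""
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#"):
                for tok in first[1:].split():
                    if tok.startswith("fs_hz="):
                        fs = float(tok.split("=", 1)[1])
                    elif tok.startswith("posture="):
                        posture = tok.split("=", 1)[1]
                df = pd.read_csv(fh)
            else:
                df = pd.read_csv(path)
        leads = {c: df[c].to_numpy(dtype=float) for c in df.columns}
        return cls(leads=leads, fs=fs, posture_label=posture)


def wilson_central_terminal(e: ElectrodePotentials) -> np.ndarray:
    """WCT = (RA + LA + LL) / 3, sample-wise."""
    ra, la, ll = (np.asarray(x, dtype=float) for x in (e.RA, e.LA, e.LL))
    if not (len(ra) == len(la) == len(ll)):
        raise ShapeError("RA/LA/LL length mismatch")
    return (ra + la + ll) / 3.0


def derive_12_from_electrodes(e: ElectrodePotentials, posture_label: str = "") -> LeadSetRecording:
    """All 12 leads from the nine formula-relevant electrode potentials."""
    ra = np.asarray(e.RA, dtype=float)
    la = np.asarray(e.LA, dtype=float)
    ll = np.asarray(e.LL, dtype=float)
    wct = wilson_central_terminal(e)
    leads: dict[str, np.ndarray] = {
        "I": la - ra,
        "II": ll - ra,
        "III": ll - la,
        "aVR": ra - (la + ll) / 2.0,
        "aVL": la - (ra + ll) / 2.0,
        "aVF": ll - (ra + la) / 2.0,
    }
    for name in PRECORDIAL:
        leads[name] = np.asarray(getattr(e, f"{name}e"), dtype=float) - wct
    ordered = {k: leads[k] for k in LEADS_12}
    return LeadSetRecording(leads=ordered, fs=e.fs, posture_label=posture_label)


def channels_from_electrodes(e: ElectrodePotentials, posture_label: str = "") -> LeadSetRecording:
    """The 8-channel subset the device transmits (I, II, WCT-referenced V1..V6)."""
    full = derive_12_from_electrodes(e, posture_label=posture_label)
    return LeadSetRecording(
        leads={k: full.leads[k] for k in CHANNELS_8},
        fs=e.fs,
        posture_label=posture_label,
    )


def derive_12_from_channels(r: LeadSetRecording) -> LeadSetRecording:
    """12 leads from the transmitted 8; derived-lead masks are conjunctions."""
    missing = [c for c in CHANNELS_8 if c not in r.leads]
    if missing:
        raise ConfigurationError(f"missing source channels: {missing}")
    one = np.asarray(r.leads["I"], dtype=float).copy()
    two = np.asarray(r.leads["II"], dtype=float).copy()
    leads = {
        "I": one,
        "II": two,
        "III": two - one,
        "aVR": -(one + two) / 2.0,
        "aVL": one - two / 2.0,
        "aVF": two - one / 2.0,
    }
    for name in PRECORDIAL:
        leads[name] = r.leads[name]
    mask_12 = {}
    limb_mask = r.valid_mask["I"] & r.valid_mask["II"]
    for name in LEADS_12:
        if name in DERIVED_SOURCES:
            mask_12[name] = limb_mask.copy()
        else:
            mask_12[name] = r.valid_mask[name].copy()
    return LeadSetRecording(
        leads={k: np.array(leads[k], dtype=float, copy=True) for k in LEADS_12},
        fs=r.fs,
        valid_mask=mask_12,
        posture_label=r.posture_label,
    )
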
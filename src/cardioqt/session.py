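"""Session orchestration: full-pipeline analysis, SQLite storage, export.

``run_analysis`` executes decode -> lead-off masking -> 12-lead derivation ->
conditioning -> R detection -> delineation -> repolarization -> feature
vector, with stage-level counters so no beat or lead is dropped silently.
One session corresponds to one posture recording; postures are never pooled.
"""

from __future__ import annotations

import json
import sqlite3
import uuid
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np

from . import packet_codec
from .feature_report import FeatureVector, build_feature_vector, default_reference_ranges, flag_against_reference
from .lead_derivation import LeadSetRecording, derive_12_from_channels, CHANNELS_8
from .preprocess import FilterSpec, apply_leadoff_mask, condition, counts_to_microvolts, leadoff_intervals
from .repolarization import RepolConfig, analyze_repolarization
from .rhythm_morphology import (
    InsufficientDataError,
    delineate_lead,
    detect_r_peaks,
    morphology_metrics,
    rhythm_metrics,
    MorphologySummary,
    RhythmSummary,
)


@dataclass
class AnalysisConfig:
    """Complete, serializable snapshot of every analysis setting."""

    fs: float = 500.0
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    repol: RepolConfig = field(default_factory=RepolConfig)
    posture_label: str = ""

    def to_dict(self) -> dict:
        d = {"fs": self.fs, "posture_label": self.posture_label}
        d["filter_spec"] = asdict(self.filter_spec)
        r = asdict(self.repol)
        r["leads_considered"] = list(r["leads_considered"])
        d["repol"] = r
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        r = dict(d.get("repol", {}))
        if "leads_considered" in r:
            r["leads_considered"] = tuple(r["leads_considered"])
        return cls(
            fs=d.get("fs", 500.0),
            filter_spec=FilterSpec(**d.get("filter_spec", {})),
            repol=RepolConfig(**r),
            posture_label=d.get("posture_label", ""),
        )


@dataclass
class SessionRecord:
    session_id: str
    posture_label: str
    source: str
    started_at: str
    ended_at: str
    pause_intervals: list[tuple[str, float, float, str]]  # (channel, start_s, end_s, cause)
    feature_vector: FeatureVector
    per_lead: dict  # lead -> {n_valid, n_total, qt_median_ms, eligible, reason}
    flags: dict  # parameter -> flag string
    config: dict
    stage_log: dict
    beats: dict = field(default_factory=dict)  # lead -> list of beat dicts


def _recording_from_stream(stream: packet_codec.RawFrameStream, fs: float) -> LeadSetRecording:
    mat = counts_to_microvolts(stream.sample_matrix())
    leads = {ch: mat[:, i].copy() for i, ch in enumerate(CHANNELS_8)}
    return LeadSetRecording(leads=leads, fs=fs)


def run_analysis(
    source,
    config: AnalysisConfig | None = None,
    recording_id: str | None = None,
) -> SessionRecord:
    """Analyze a packet-stream file/bytes or an in-memory recording.

    Total signal loss yields an all-NA feature vector, never a crash.
    """
    config = config or AnalysisConfig()
    started = datetime.now(timezone.utc).isoformat()
    log: dict = {}
    pauses: list[tuple[str, float, float, str]] = []

    if isinstance(source, LeadSetRecording):
        rec8 = source
        src_desc = "matrix"
    else:
        if isinstance(source, (bytes, bytearray)):
            raw = bytes(source)
            src_desc = "stream:<bytes>"
        else:
            path = Path(source)
            if not path.exists() or path.stat().st_size == 0:
                raise IOError(f"unreadable or empty input file: {path}")
            if path.suffix.lower() == ".csv":
                rec = LeadSetRecording.from_csv(path)
                return run_analysis(rec, config, recording_id=recording_id or path.stem)
            raw = path.read_bytes()
            src_desc = f"stream:{path}"
        stream = packet_codec.resync_stream(raw)
        log["frames"] = len(stream)
        log["discarded_bytes"] = stream.discard_count
        if len(stream) == 0:
            raise IOError(f"no decodable frames in input ({src_desc})")
        rec8 = _recording_from_stream(stream, config.fs)
        rec8 = apply_leadoff_mask(rec8, stream)
        pauses = [(ch, s, e, "lead_off") for ch, s, e in leadoff_intervals(stream, config.fs)]

    rec8 = LeadSetRecording(
        leads=rec8.leads, fs=rec8.fs, valid_mask=rec8.valid_mask,
        posture_label=config.posture_label or rec8.posture_label,
    )
    rec12 = derive_12_from_channels(rec8)
    cond = condition(rec12, config.filter_spec)
    log["n_samples"] = cond.n_samples

    analysis_leads = tuple(dict.fromkeys(config.repol.leads_considered + ("II",)))
    beats = {}
    n_beats_log, n_excl_log = {}, {}
    for name in analysis_leads:
        x = cond.leads[name]
        mask = cond.valid_mask[name]
        try:
            peaks = detect_r_peaks(x, cond.fs, valid_mask=mask)
        except InsufficientDataError:
            peaks = np.array([], dtype=int)
        anns = delineate_lead(x, peaks, cond.fs, valid_mask=mask)
        beats[name] = anns
        n_beats_log[name] = len(anns)
        n_excl_log[name] = {
            reason.value: sum(1 for b in anns if b.exclusion_reason.value == reason.value and not b.valid)
            for reason in {b.exclusion_reason for b in anns if not b.valid}
        }
    log["beats_detected"] = n_beats_log
    log["beats_excluded"] = n_excl_log

    lead_ii_peaks = np.array([b.r_index for b in beats.get("II", [])], dtype=int)
    rhythm = rhythm_metrics(lead_ii_peaks, cond.fs)
    morph = morphology_metrics(beats.get("II", []), cond.leads["II"], cond.fs)
    repol = analyze_repolarization(cond, beats, config.repol)
    log["eligible_leads"] = repol.n_eligible_leads

    rid = recording_id or str(uuid.uuid4())[:8]
    features = build_feature_vector(
        rhythm, morph, repol, recording_id=rid, posture_label=config.posture_label,
    )
    flags = {k: v.value for k, v in flag_against_reference(features).items()}

    per_lead = {
        name: {
            "n_valid": est.n_valid,
            "n_total": est.n_total,
            "qt_median_ms": est.qt_median_ms,
            "eligible": est.eligible,
            "reason": est.ineligibility_reason,
        }
        for name, est in repol.per_lead.items()
    }
    beats_out = {
        name: [
            {
                "r_index": b.r_index,
                "q_onset": b.q_onset,
                "qrs_offset": b.qrs_offset,
                "t_peak": b.t_peak,
                "t_end": b.t_end,
                "valid": b.valid,
                "exclusion_reason": b.exclusion_reason.value,
            }
            for b in anns
        ]
        for name, anns in beats.items()
    }

    return SessionRecord(
        session_id=str(uuid.uuid4()),
        posture_label=config.posture_label,
        source=src_desc if not isinstance(source, LeadSetRecording) else "matrix",
        started_at=started,
        ended_at=datetime.now(timezone.utc).isoformat(),
        pause_intervals=pauses,
        feature_vector=features,
        per_lead=per_lead,
        flags=flags,
        config=config.to_dict(),
        stage_log=log,
        beats=beats_out,
    )


# ---------------------------------------------------------------- storage

_SCHEMA = """
CREATE TABLE IF NOT EXISTS sessions (
    session_id TEXT PRIMARY KEY,
    posture TEXT, source TEXT, started_at TEXT, ended_at TEXT,
    config_json TEXT, pauses_json TEXT, log_json TEXT, flags_json TEXT
);
CREATE TABLE IF NOT EXISTS features (
    session_id TEXT, name TEXT, value REAL,
    PRIMARY KEY (session_id, name)
);
CREATE TABLE IF NOT EXISTS leads (
    session_id TEXT, lead TEXT, n_valid INTEGER, n_total INTEGER,
    qt_median_ms REAL, eligible INTEGER, reason TEXT,
    PRIMARY KEY (session_id, lead)
);
CREATE TABLE IF NOT EXISTS beats (
    session_id TEXT, lead TEXT, beat INTEGER, r_index INTEGER,
    q_onset INTEGER, qrs_offset INTEGER, t_peak INTEGER, t_end INTEGER,
    valid INTEGER, exclusion_reason TEXT,
    PRIMARY KEY (session_id, lead, beat)
);
"""


class SessionStore:
    """Single-file SQLite store for analyzed sessions."""

    def __init__(self, path):
        self.path = str(path)
        self._conn = sqlite3.connect(self.path)
        self._conn.executescript(_SCHEMA)

    def close(self):
        self._conn.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self._conn.commit()
        self.close()

    def save(self, rec: SessionRecord) -> None:
        c = self._conn
        c.execute(
            "INSERT OR REPLACE INTO sessions VALUES (?,?,?,?,?,?,?,?,?)",
            (
                rec.session_id, rec.posture_label, rec.source, rec.started_at, rec.ended_at,
                json.dumps(rec.config), json.dumps(rec.pause_intervals),
                json.dumps(rec.stage_log), json.dumps(rec.flags),
            ),
        )
        for name in FeatureVector.METRICS:
            c.execute(
                "INSERT OR REPLACE INTO features VALUES (?,?,?)",
                (rec.session_id, name, getattr(rec.feature_vector, name)),
            )
        for lead, d in rec.per_lead.items():
            c.execute(
                "INSERT OR REPLACE INTO leads VALUES (?,?,?,?,?,?,?)",
                (rec.session_id, lead, d["n_valid"], d["n_total"], d["qt_median_ms"],
                 int(d["eligible"]), d["reason"]),
            )
        for lead, blist in rec.beats.items():
            for i, b in enumerate(blist):
                c.execute(
                    "INSERT OR REPLACE INTO beats VALUES (?,?,?,?,?,?,?,?,?,?)",
                    (rec.session_id, lead, i, b["r_index"], b["q_onset"], b["qrs_offset"],
                     b["t_peak"], b["t_end"], int(b["valid"]), b["exclusion_reason"]),
                )
        c.commit()

    def load_features(self, session_id: str) -> FeatureVector:
        cur = self._conn.execute(
            "SELECT posture, session_id FROM sessions WHERE session_id=?", (session_id,)
        )
        row = cur.fetchone()
        if row is None:
            raise KeyError(f"no session {session_id}")
        vals = dict(
            self._conn.execute(
                "SELECT name, value FROM features WHERE session_id=?", (session_id,)
            ).fetchall()
        )
        return FeatureVector(recording_id=session_id, posture_label=row[0], **vals)

    def session_ids(self) -> list[str]:
        return [r[0] for r in self._conn.execute("SELECT session_id FROM sessions")]


# ----------------------------------------------------------------- export

def record_to_dict(rec: SessionRecord) -> dict:
    return {
        "session_id": rec.session_id,
        "posture_label": rec.posture_label,
        "source": rec.source,
        "started_at": rec.started_at,
        "ended_at": rec.ended_at,
        "pause_intervals": [list(p) for p in rec.pause_intervals],
        "features": rec.feature_vector.to_dict(),
        "per_lead": rec.per_lead,
        "flags": rec.flags,
        "config": rec.config,
        "stage_log": rec.stage_log,
    }


def export_record(rec: SessionRecord, fmt: str, path) -> None:
    """Features + per-lead details to JSON or CSV; NA -> null / empty cell."""
    fmt = fmt.lower()
    if fmt == "json":
        Path(path).write_text(json.dumps(record_to_dict(rec), indent=2))
    elif fmt == "csv":
        d = rec.feature_vector.to_dict()
        cols = ["session_id"] + list(d.keys())
        row = [rec.session_id] + ["" if d[k] is None else d[k] for k in d]
        with open(path, "w") as fh:
            fh.write(",".join(cols) + "\n")
            fh.write(",".join(str(v) for v in row) + "\n")
    else:
        raise ValueError(f"unsupported export format {fmt!r} (use csv or json)")


def import_record_json(path) -> dict:
    return json.loads(Path(path).read_text())


# --------------------------------------------------- schema-lite validation

def schema_path() -> Path:
    return Path(__file__).parent / "data" / "session_record.schema.json"


def validate_record(obj: dict, schema: dict | None = None, _loc: str = "$") -> list[str]:
    """Minimal structural validation against the shipped schema.

    Supports the subset used by the schema: type, required, properties.
    Returns a list of violation messages (empty when valid).
    """
    if schema is None:
        schema = json.loads(schema_path().read_text())
    errors: list[str] = []
    typ = schema.get("type")
    typemap = {
        "object": dict, "array": list, "string": str,
        "number": (int, float), "integer": int, "boolean": bool,
    }
    if typ is not None:
        allowed = typ if isinstance(typ, list) else [typ]
        ok = any(
            (obj is None) if t == "null" else isinstance(obj, typemap[t]) and not (t == "number" and isinstance(obj, bool))
            for t in allowed
        )
        if not ok:
            errors.append(f"{_loc}: expected {typ}, got {type(obj).__name__}")
            return errors
    if isinstance(obj, dict):
        for req in schema.get("required", []):
            if req not in obj:
                errors.append(f"{_loc}: missing required key {req!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in obj:
                errors.extend(validate_record(obj[key], sub, f"{_loc}.{key}"))
    return errors
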
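{
  "type": "object",
  "required": ["session_id", "posture_label", "features", "per_lead", "flags", "config"],
  "properties": {
    "session_id": {"type": "string"},
    "posture_label": {"type": "string"},
    "source": {"type": "string"},
    "pause_intervals": {"type": "array"},
    "features": {
      "type": "object",
      "required": ["qtc_ms", "qtd_ms", "t_amplitude_mv", "st_shift_mv", "hr_bpm",
                   "sdnn_ms", "qt_ms", "p_duration_ms", "qrs_width_ms", "rr_mean_s"],
      "properties": {
        "recording_id": {"type": "string"},
        "posture_label": {"type": "string"},
        "qtc_ms": {"type": ["number", "null"]},
        "qtd_ms": {"type": ["number", "null"]},
        "t_amplitude_mv": {"type": ["number", "null"]},
        "st_shift_mv": {"type": ["number", "null"]},
        "hr_bpm": {"type": ["number", "null"]},
        "sdnn_ms": {"type": ["number", "null"]},
        "qt_ms": {"type": ["number", "null"]},
        "p_duration_ms": {"type": ["number", "null"]},
        "qrs_width_ms": {"type": ["number", "null"]},
        "rr_mean_s": {"type": ["number", "null"]}
      }
    },
    "per_lead": {"type": "object"},
    "flags": {"type": "object"},
    "config": {"type": "object"},
    "stage_log": {"type": "object"}
  }
}
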
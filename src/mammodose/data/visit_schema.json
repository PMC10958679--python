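{
  "format": "visit metadata CSV (one row per image)",
  "schema_version": "1.0",
  "columns": {
    "woman_id": {"type": "string", "required": true},
    "visit_id": {"type": "string", "required": true, "note": "rows sharing (woman_id, visit_id) form one visit"},
    "age_years": {"type": "integer", "required": true, "range": [40, 75], "note": "ages outside the range are warned and skipped"},
    "laterality": {"type": "string", "required": true, "values": ["L", "R"]},
    "view": {"type": "string", "required": true, "values": ["MLO", "CC"]},
    "mbd_pct": {"type": "number", "required": true, "range": [0, 100], "units": "%", "note": "mammographic breast density (area percent)"},
    "cbt_mm": {"type": "number", "required": true, "range_exclusive": [0, 200], "units": "mm", "note": "compressed breast thickness"},
    "kvp": {"type": "integer", "required": true, "range": [20, 49], "units": "kVp"},
    "mas": {"type": "number", "required": true, "minimum_exclusive": 0, "units": "mAs"},
    "target_filter": {"type": "string", "required": true, "values": ["W/Rh", "W/Ag"]},
    "detector_id": {"type": "string", "required": true, "note": "selects the QA-config block"},
    "model_name": {"type": "string", "required": true},
    "hvl_mm_al": {"type": "number", "required": false, "units": "mm Al", "note": "per-image measured HVL override; otherwise modelled from kVp"}
  }
}
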
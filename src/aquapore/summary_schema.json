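{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "aquapore run summary",
  "type": "object",
  "required": [
    "aquapore_version",
    "config_hash",
    "seed",
    "n_frames",
    "n_molecules",
    "layer_boundaries_r",
    "layer_labels",
    "stages_run",
    "per_layer",
    "wall_time_s"
  ],
  "properties": {
    "aquapore_version": {"type": "string"},
    "config_hash": {"type": "string"},
    "seed": {"type": "integer"},
    "n_frames": {"type": "integer"},
    "n_molecules": {"type": "integer"},
    "layer_boundaries_r": {"type": "array"},
    "layer_labels": {"type": "array"},
    "stages_run": {"type": "array"},
    "per_layer": {"type": "object"},
    "dynamics": {"type": "object"},
    "wall_time_s": {"type": "number"}
  }
}
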
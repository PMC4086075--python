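{
  "domain": "bacteria",
  "root": "cytoplasmic_vs_exported",
  "nodes": {
    "cytoplasmic_vs_exported": ["cytosolic_side", "exported_side"],
    "cytosolic_side": ["cytosol", "plasma membrane"],
    "exported_side": ["periplasmic space", "envelope_vs_external"],
    "envelope_vs_external": ["outer membrane", "appendage_vs_secreted"],
    "appendage_vs_secreted": ["fimbrium", "extra-cellular"]
  }
}
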
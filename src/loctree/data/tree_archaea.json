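{
  "domain": "archaea",
  "root": "intracellular_vs_exported",
  "nodes": {
    "intracellular_vs_exported": ["cytosol", "membrane_vs_secreted"],
    "membrane_vs_secreted": ["plasma membrane", "extra-cellular"]
  }
}
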
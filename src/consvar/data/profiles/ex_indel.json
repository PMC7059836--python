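{
  "name": "ex_indel",
  "fail_label": "GIABFILTER",
  "description": "Hard filter for INDELs called by bcftools on whole-exome data (no depth rule).",
  "rules": [
    {"annotation": "MQ", "direction": "reject_below", "threshold": 45},
    {"annotation": "MQ0F", "direction": "reject_above", "threshold": 0.002034686},
    {"annotation": "HOB", "direction": "reject_above", "threshold": 0.269603},
    {"annotation": "SGB", "direction": "reject_above", "threshold": 53165.5},
    {"annotation": "SGB", "direction": "reject_below", "threshold": -85919.729},
    {"annotation": "IMF", "direction": "reject_below", "threshold": 0.3323922},
    {"annotation": "QUAL", "direction": "reject_below", "threshold": 20}
  ]
}
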
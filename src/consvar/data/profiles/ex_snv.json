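{
  "name": "ex_snv",
  "fail_label": "GIABFILTER",
  "description": "Hard filter for SNVs called by bcftools on whole-exome data.",
  "rules": [
    {"annotation": "DP", "direction": "reject_above", "threshold": 656519},
    {"annotation": "MQ", "direction": "reject_below", "threshold": 38},
    {"annotation": "MQ0F", "direction": "reject_above", "threshold": 0.0146629},
    {"annotation": "HOB", "direction": "reject_above", "threshold": 0.1536016},
    {"annotation": "SGB", "direction": "reject_above", "threshold": 57489.21},
    {"annotation": "SGB", "direction": "reject_below", "threshold": -226326.93},
    {"annotation": "QUAL", "direction": "reject_below", "threshold": 20}
  ]
}
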
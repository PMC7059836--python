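{
  "name": "lc_indel",
  "fail_label": "GIABFILTER",
  "description": "Hard filter for INDELs called by bcftools on low-coverage WGS data.",
  "rules": [
    {"annotation": "DP", "direction": "reject_above", "threshold": 23758},
    {"annotation": "MQ", "direction": "reject_below", "threshold": 41},
    {"annotation": "MQ0F", "direction": "reject_above", "threshold": 0.009913696},
    {"annotation": "HOB", "direction": "reject_above", "threshold": 0.20265508},
    {"annotation": "SGB", "direction": "reject_above", "threshold": 2143.8876},
    {"annotation": "SGB", "direction": "reject_below", "threshold": -29513.557},
    {"annotation": "IDV", "direction": "reject_above", "threshold": 51},
    {"annotation": "IMF", "direction": "reject_below", "threshold": 0.387097},
    {"annotation": "QUAL", "direction": "reject_below", "threshold": 20}
  ]
}
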
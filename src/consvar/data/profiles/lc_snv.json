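{
  "name": "lc_snv",
  "fail_label": "GIABFILTER",
  "description": "Hard filter for SNVs called by bcftools on low-coverage WGS data; cutoffs derived from TP/FP annotation distributions against the NA12878 gold standard.",
  "rules": [
    {"annotation": "DP", "direction": "reject_above", "threshold": 24304},
    {"annotation": "MQ", "direction": "reject_below", "threshold": 34},
    {"annotation": "MQ0F", "direction": "reject_above", "threshold": 0.049737},
    {"annotation": "HOB", "direction": "reject_above", "threshold": 0.1643732},
    {"annotation": "SGB", "direction": "reject_above", "threshold": 2347.043},
    {"annotation": "SGB", "direction": "reject_below", "threshold": -64440.286},
    {"annotation": "QUAL", "direction": "reject_below", "threshold": 20}
  ]
}
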
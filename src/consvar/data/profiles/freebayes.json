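{
  "name": "freebayes",
  "fail_label": "QUALFILTER",
  "description": "Quality hard filter for the Freebayes call set: reject when QUAL < 1 (strict, matching the production filter expression).",
  "rules": [
    {"annotation": "QUAL", "direction": "reject_below", "threshold": 1}
  ]
}
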
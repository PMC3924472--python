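{
  "attributes": [
    ["deadline_bucket", ["overdue", "today", "within_week", "later", "none"]],
    ["requested_by", ["father", "mother", "someone_else", "nobody"]],
    ["area", ["academic", "personal", "family", "leisure"]]
  ]
}
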
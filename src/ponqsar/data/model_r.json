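{
  "response_name": "log_rate_r",
  "intercept": 4.879,
  "terms": [
    ["SIC0", -9.472],
    ["Mor17m", 5.054],
    ["Mor22m", -3.861],
    ["Mor25m", -2.763]
  ],
  "train_ids": null,
  "fit_seed": null,
  "provenance": "published-fixture"
}
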
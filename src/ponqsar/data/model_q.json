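{
  "response_name": "log_rate_q",
  "intercept": -0.487,
  "terms": [
    ["Mor10m", 2.066],
    ["Mor17m", 3.970],
    ["E1v", 3.319],
    ["H8m", -25.907]
  ],
  "train_ids": null,
  "fit_seed": null,
  "provenance": "published-fixture"
}
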
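{
  "label": "high_N0",
  "generation_time_years": 5,
  "comment": "PLACEHOLDER epochs: log-spaced diploid-Ne decline from an ancestral size of 70,000 at ~2,000 generations (domestication) to the present-day size; substitute published Holstein epoch estimates here to reproduce literature values.",
  "epochs": [
    [
      0,
      793.0
    ],
    [
      50,
      1673.3
    ],
    [
      125,
      3530.9
    ],
    [
      250,
      7450.5
    ],
    [
      500,
      15721.3
    ],
    [
      1000,
      33173.7
    ],
    [
      2000,
      70000.0
    ]
  ]
}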
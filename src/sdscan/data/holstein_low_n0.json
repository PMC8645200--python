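{
  "label": "low_N0",
  "generation_time_years": 5,
  "comment": "PLACEHOLDER epochs: log-spaced diploid-Ne decline from an ancestral size of 70,000 at ~2,000 generations (domestication) to the present-day size; substitute published Holstein epoch estimates here to reproduce literature values.",
  "epochs": [
    [
      0,
      49.0
    ],
    [
      50,
      164.4
    ],
    [
      125,
      551.9
    ],
    [
      250,
      1852.0
    ],
    [
      500,
      6215.3
    ],
    [
      1000,
      20858.4
    ],
    [
      2000,
      70000.0
    ]
  ]
}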
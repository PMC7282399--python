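{
  "source": "published standards (n=1181 pooled normative cohort)",
  "directions": {
    "cognitive": "higher_is_better",
    "fine_motor": "higher_is_better",
    "gross_motor": "higher_is_better",
    "language": "higher_is_better",
    "positive_behaviour": "higher_is_better",
    "negative_behaviour": "lower_is_better"
  },
  "boundaries": {
    "cognitive":          {"c3": 27.4, "c10": 38.5, "c90": 92.6, "c97": 99.6},
    "fine_motor":         {"c3": 17.5, "c10": 25.7, "c90": 100.0, "c97": 100.0},
    "gross_motor":        {"c3": 31.1, "c10": 51.7, "c90": 100.0, "c97": 100.0},
    "language":           {"c3": 12.1, "c10": 17.8, "c90": 95.1, "c97": 100.0},
    "positive_behaviour": {"c3": 37.8, "c10": 51.4, "c90": 100.0, "c97": 100.0},
    "negative_behaviour": {"c3": 0.0, "c10": 0.0, "c90": 50.0, "c97": 76.5}
  },
  "full_centiles": {
    "cognitive":          {"c3": 27.4, "c10": 38.5, "c25": 62.2, "c50": 79.5, "c75": 88.8, "c90": 92.6, "c97": 99.6},
    "fine_motor":         {"c3": 17.5, "c10": 25.7, "c25": 74.2, "c50": 91.4, "c75": 100.0, "c90": 100.0, "c97": 100.0},
    "gross_motor":        {"c3": 31.1, "c10": 51.7, "c25": 66.7, "c50": 81.6, "c75": 100.0, "c90": 100.0, "c97": 100.0},
    "language":           {"c3": 12.1, "c10": 17.8, "c25": 45.7, "c50": 71.7, "c75": 88.5, "c90": 95.1, "c97": 100.0},
    "positive_behaviour": {"c3": 37.8, "c10": 51.4, "c25": 70.0, "c50": 90.0, "c75": 100.0, "c90": 100.0, "c97": 100.0},
    "negative_behaviour": {"c3": 0.0, "c10": 0.0, "c25": 0.0, "c50": 25.0, "c75": 25.0, "c90": 50.0, "c97": 76.5}
  }
}
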
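{
  "comment": "Keywords deciding the Alive and Healthy property scores of a living-status mention. A property with no keyword hit defaults to NA = 1; the total living-status score is alive * healthy.",
  "alive_yes": ["alive", "living"],
  "alive_no": ["dead", "die", "deceased", "death", "died", "stillborn", "passed away"],
  "healthy_yes": ["good", "health", "without problems", "healthy", "well"],
  "scores": {"yes": 2, "na": 1, "no": 0}
}
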
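{
  "comment": "Negation cue keywords searched in an observation's sentence context, and reversal phrases that flip a cue-triggered negation back to Non_Negated. Both lists are user-extensible.",
  "cues": ["no", "never", "not", "none", "negative", "neither", "nor", "unremarkable", "deny"],
  "reversal_phrases": ["apart from", "except for"]
}
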
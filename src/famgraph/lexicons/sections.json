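{
  "comment": "Regex patterns (case-insensitive) classifying section headings. A heading opens a section that lasts until the next heading.",
  "maternal": ["maternal\\s+family\\s+history"],
  "paternal": ["paternal\\s+family\\s+history"],
  "exclude": ["partner", "in-law", "husband", "wife", "spouse"]
}
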
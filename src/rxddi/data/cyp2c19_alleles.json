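{
  "*1": "normal",
  "*2": "no_function",
  "*3": "no_function",
  "*17": "increased"
}
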
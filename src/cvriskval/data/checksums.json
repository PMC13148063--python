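{
  "pce_coefficients.csv": "cc27a2b2a43e2ca9f57493c94985e9050cb2257c222c41cec421c47ab156e792",
  "prevent_addon_terms_synthetic.csv": "edbbdb45732d5f167cb31fbe6f5c8fa8f8050694501665c02f91d5c85e143120",
  "prevent_base_coefficients.csv": "6a9f2d4fb6081de5979c7b30efcba59cb727f866d8bbbfb0b35fb41858eddb80"
}
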
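{
  "file": "observer_tables_synthetic.csv",
  "sha256": "e5ef85110ad3442c1f87ac6d5c62bc4f978cc61fd2d6cd7eb46bd20202145d02",
  "provenance": "synthetic-analytic-v1",
  "grid": "380-780 nm, 5 nm step"
}
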
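expr1:
  control_rep1: control
  control_rep2: control
  test_rep1: test
  test_rep2: test
expr2:
  control_rep1: control
  control_rep2: control
  test_rep1: test
  test_rep2: test
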
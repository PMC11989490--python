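# English negation rule set (NegEx-style). All phrases lower-case.
pre_triggers:
  - "no"
  - "not"
  - "without"
  - "denies"
  - "denied"
  - "negative for"
  - "no evidence of"
  - "free of"
post_triggers:
  - "ruled out"
  - "absent"
  - "negative"
terminators:
  - "but"
  - "however"
  - "although"
  - "except"
  - ";"
scope_window: 5
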
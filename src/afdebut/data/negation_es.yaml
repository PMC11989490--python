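# Spanish negation rule set (NegEx-style). All phrases lower-case, unaccented.
pre_triggers:
  - "no"
  - "sin"
  - "niega"
  - "descarta"
  - "ausencia de"
  - "sin evidencia de"
  - "sin datos de"
post_triggers:
  - "descartado"
  - "descartada"
  - "ausente"
  - "negativo"
  - "negativa"
terminators:
  - "pero"
  - "aunque"
  - "salvo"
  - "excepto"
  - ";"
scope_window: 5
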
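# Spanish discharge-report heading lexicon: section label -> surface forms.
# Matching is case/accent-insensitive; a trailing colon is optional.
Header:
  - "DATOS DEL EPISODIO"
  - "CABECERA"
ReasonForConsultation:
  - "MOTIVO DE CONSULTA"
  - "MOTIVO DE INGRESO"
PersonalHistory:
  - "ANTECEDENTES PERSONALES"
  - "ANTECEDENTES"
CurrentIllness:
  - "ENFERMEDAD ACTUAL"
  - "HISTORIA ACTUAL"
GeneralExploration:
  - "EXPLORACION GENERAL"
  - "EXPLORACION FISICA"
ComplementaryTests:
  - "PRUEBAS COMPLEMENTARIAS"
  - "EXPLORACIONES COMPLEMENTARIAS"
Diagnosis:
  - "DIAGNOSTICO"
  - "DIAGNOSTICOS"
  - "JUICIO CLINICO"
Treatment:
  - "TRATAMIENTO"
  - "TRATAMIENTO AL ALTA"
Evolution:
  - "EVOLUCION"
  - "EVOLUCION CLINICA"
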
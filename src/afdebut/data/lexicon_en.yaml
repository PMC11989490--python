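# English discharge-report heading lexicon: section label -> surface forms.
Header:
  - "EPISODE DETAILS"
  - "HEADER"
ReasonForConsultation:
  - "REASON FOR CONSULTATION"
  - "REASON FOR ADMISSION"
PersonalHistory:
  - "PERSONAL HISTORY"
  - "PAST MEDICAL HISTORY"
CurrentIllness:
  - "CURRENT ILLNESS"
  - "HISTORY OF PRESENT ILLNESS"
GeneralExploration:
  - "GENERAL EXPLORATION"
  - "PHYSICAL EXAMINATION"
ComplementaryTests:
  - "COMPLEMENTARY TESTS"
  - "INVESTIGATIONS"
Diagnosis:
  - "DIAGNOSIS"
  - "CLINICAL IMPRESSION"
Treatment:
  - "TREATMENT"
  - "TREATMENT AT DISCHARGE"
Evolution:
  - "EVOLUTION"
  - "CLINICAL COURSE"
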
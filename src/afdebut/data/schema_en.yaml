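# English demonstrator variable schema; mirrors the Spanish bank.
af:
  patterns:
    - "atrial fibrillation"
    - "\\bafib\\b"
  onset_qualifiers:
    - "new[\\s-]?onset"
    - "de novo"
    - "first episode"
    - "\\bdebut\\b"
variables:
  - variable_id: age
    value_type: numeric
    variable_class: demographic
    target_sections: [ReasonForConsultation, CurrentIllness]
    patterns:
      - "(?:patient aged|\\bage\\b[:]?)\\s*(?P<value>\\d{1,3})"
  - variable_id: sex
    value_type: categorical
    variable_class: demographic
    target_sections: [ReasonForConsultation, CurrentIllness]
    patterns:
      - regex: "\\bmale\\b|\\bman\\b"
        value: male
      - regex: "\\bfemale\\b|\\bwoman\\b"
        value: female
  - variable_id: diabetes
    value_type: boolean
    variable_class: history
    target_sections: [PersonalHistory, Diagnosis]
    patterns: ["\\bdiabetes\\b|\\bdm\\b"]
  - variable_id: hypertension
    value_type: boolean
    variable_class: history
    target_sections: [PersonalHistory, Diagnosis]
    patterns: ["\\bhypertension\\b|\\bhtn\\b"]
  - variable_id: heart_failure
    value_type: boolean
    variable_class: history
    target_sections: [PersonalHistory, Diagnosis]
    patterns: ["heart failure|\\bchf\\b"]
  - variable_id: copd
    value_type: boolean
    variable_class: history
    target_sections: [PersonalHistory, Diagnosis]
    patterns: ["\\bcopd\\b|chronic obstructive pulmonary disease"]
  - variable_id: stroke
    value_type: boolean
    variable_class: history
    target_sections: [PersonalHistory, Diagnosis]
    patterns: ["\\bstroke\\b|\\bcva\\b"]
  - variable_id: ckd
    value_type: boolean
    variable_class: history
    target_sections: [PersonalHistory, Diagnosis]
    patterns: ["chronic kidney disease|\\bckd\\b"]
  - variable_id: hyperthyroidism
    value_type: boolean
    variable_class: history
    target_sections: [PersonalHistory, Diagnosis]
    patterns: ["hyperthyroidism"]
  - variable_id: sleep_apnea
    value_type: boolean
    variable_class: history
    target_sections: [PersonalHistory, Diagnosis]
    patterns: ["sleep apnea|\\bosa\\b"]
  - variable_id: creatinine
    value_type: numeric
    variable_class: lab
    target_sections: [ComplementaryTests]
    canonical_unit: "mg/dl"
    unit_factors: {"mg/dl": 1.0, "umol/l": 0.011312}
    patterns:
      - "(?:serum )?creatinine(?: of)?\\s*[:]?\\s*(?P<value>\\d+(?:[.,]\\d+)?)\\s*(?P<unit>mg/dl|umol/l)?"
  - variable_id: hemoglobin
    value_type: numeric
    variable_class: lab
    target_sections: [ComplementaryTests]
    canonical_unit: "g/dl"
    unit_factors: {"g/dl": 1.0}
    patterns:
      - "(?:hemoglobin|\\bhb\\b)(?: of)?\\s*[:]?\\s*(?P<value>\\d+(?:[.,]\\d+)?)\\s*(?P<unit>g/dl)?"
  - variable_id: tsh
    value_type: numeric
    variable_class: lab
    target_sections: [ComplementaryTests]
    canonical_unit: "mui/l"
    unit_factors: {"mui/l": 1.0, "uui/ml": 1.0}
    patterns:
      - "\\btsh\\b(?: of)?\\s*[:]?\\s*(?P<value>\\d+(?:[.,]\\d+)?)\\s*(?P<unit>mui/l|uui/ml)?"
  - variable_id: potassium
    value_type: numeric
    variable_class: lab
    target_sections: [ComplementaryTests]
    canonical_unit: "mmol/l"
    unit_factors: {"mmol/l": 1.0, "meq/l": 1.0}
    patterns:
      - "(?:potassium|\\bk\\b)(?: of)?\\s*[:]?\\s*(?P<value>\\d+(?:[.,]\\d+)?)\\s*(?P<unit>mmol/l|meq/l)?"
  - variable_id: glucose
    value_type: numeric
    variable_class: lab
    target_sections: [ComplementaryTests]
    canonical_unit: "mg/dl"
    unit_factors: {"mg/dl": 1.0}
    patterns:
      - "(?:fasting )?glucose(?: of)?\\s*[:]?\\s*(?P<value>\\d+(?:[.,]\\d+)?)\\s*(?P<unit>mg/dl)?"
  - variable_id: lvef
    value_type: numeric
    variable_class: echo
    target_sections: [ComplementaryTests]
    canonical_unit: "%"
    unit_factors: {"%": 1.0}
    patterns:
      - "(?:\\blvef\\b|ejection fraction)(?: of)?\\s*[:]?\\s*(?P<value>\\d+(?:[.,]\\d+)?)\\s*(?P<unit>%)?"
  - variable_id: la_diameter
    value_type: numeric
    variable_class: echo
    target_sections: [ComplementaryTests]
    canonical_unit: "mm"
    unit_factors: {"mm": 1.0}
    patterns:
      - "(?:left atrium|left atrial diameter|\\bla\\b)(?: of)?\\s*[:]?\\s*(?P<value>\\d+(?:[.,]\\d+)?)\\s*(?P<unit>mm)"
  - variable_id: anticoagulant
    value_type: medication
    variable_class: medication
    target_sections: [Treatment]
    patterns:
      - "\\b(?:apixaban|rivaroxaban|edoxaban|dabigatran|acenocoumarol|warfarin)\\b"
    atc_map:
      apixaban: B01AF02
      rivaroxaban: B01AF01
      edoxaban: B01AF03
      dabigatran: B01AE07
      acenocoumarol: B01AA07
      warfarin: B01AA03
  - variable_id: beta_blocker
    value_type: medication
    variable_class: medication
    target_sections: [Treatment]
    patterns:
      - "\\b(?:bisoprolol|atenolol|carvedilol|metoprolol)\\b"
    atc_map:
      bisoprolol: C07AB07
      atenolol: C07AB03
      carvedilol: C07AG02
      metoprolol: C07AB02
  - variable_id: antiarrhythmic
    value_type: medication
    variable_class: medication
    target_sections: [Treatment]
    patterns:
      - "\\b(?:amiodarone|flecainide|dronedarone)\\b"
    atc_map:
      amiodarone: C01BD01
      flecainide: C01BC04
      dronedarone: C01BD07
  - variable_id: cardioversion
    value_type: boolean
    variable_class: procedure
    target_sections: [Evolution, CurrentIllness]
    patterns: ["cardioversion"]
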
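# Spanish demonstrator variable schema (~20 variables). Patterns are applied
# to accent-folded, lower-cased text inside the listed target sections only.
# The format scales to a full clinical pattern bank; this bank covers the
# variable classes the pipeline distinguishes (demographic, history, lab,
# echo, medication, procedure).
af:
  patterns:
    - "fibrilacion auricular"
    - "\\bfa\\b"
    - "\\bacxfa\\b"
  onset_qualifiers:
    - "de novo"
    - "primer episodio"
    - "\\bdebut\\b"
    - "de nueva aparicion"
variables:
  - variable_id: age
    value_type: numeric
    variable_class: demographic
    target_sections: [ReasonForConsultation, CurrentIllness]
    patterns:
      - "(?:paciente de|edad[:]?)\\s*(?P<value>\\d{1,3})\\s*anos"
  - variable_id: sex
    value_type: categorical
    variable_class: demographic
    target_sections: [ReasonForConsultation, CurrentIllness]
    patterns:
      - regex: "\\bvaron\\b|\\bhombre\\b|\\bmasculino\\b"
        value: male
      - regex: "\\bmujer\\b|\\bfemenina\\b|\\bfemenino\\b"
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
    patterns: ["\\bhipertension(?: arterial)?\\b|\\bhta\\b"]
  - variable_id: heart_failure
    value_type: boolean
    variable_class: history
    target_sections: [PersonalHistory, Diagnosis]
    patterns: ["insuficiencia cardiaca|\\bicc\\b"]
  - variable_id: copd
    value_type: boolean
    variable_class: history
    target_sections: [PersonalHistory, Diagnosis]
    patterns: ["\\bepoc\\b|enfermedad pulmonar obstructiva cronica"]
  - variable_id: stroke
    value_type: boolean
    variable_class: history
    target_sections: [PersonalHistory, Diagnosis]
    patterns: ["\\bictus\\b|\\bacv\\b|accidente cerebrovascular"]
  - variable_id: ckd
    value_type: boolean
    variable_class: history
    target_sections: [PersonalHistory, Diagnosis]
    patterns: ["enfermedad renal cronica|\\berc\\b"]
  - variable_id: hyperthyroidism
    value_type: boolean
    variable_class: history
    target_sections: [PersonalHistory, Diagnosis]
    patterns: ["hipertiroidismo"]
  - variable_id: sleep_apnea
    value_type: boolean
    variable_class: history
    target_sections: [PersonalHistory, Diagnosis]
    patterns: ["\\bsaos\\b|apnea(?: obstructiva)? del sueno"]
  - variable_id: creatinine
    value_type: numeric
    variable_class: lab
    target_sections: [ComplementaryTests]
    canonical_unit: "mg/dl"
    unit_factors: {"mg/dl": 1.0, "umol/l": 0.011312}
    patterns:
      - "creatinina(?: serica)?(?: de)?\\s*[:]?\\s*(?P<value>\\d+(?:[.,]\\d+)?)\\s*(?P<unit>mg/dl|umol/l)?"
  - variable_id: hemoglobin
    value_type: numeric
    variable_class: lab
    target_sections: [ComplementaryTests]
    canonical_unit: "g/dl"
    unit_factors: {"g/dl": 1.0}
    patterns:
      - "(?:hemoglobina|\\bhb\\b)(?: de)?\\s*[:]?\\s*(?P<value>\\d+(?:[.,]\\d+)?)\\s*(?P<unit>g/dl)?"
  - variable_id: tsh
    value_type: numeric
    variable_class: lab
    target_sections: [ComplementaryTests]
    canonical_unit: "mui/l"
    unit_factors: {"mui/l": 1.0, "uui/ml": 1.0}
    patterns:
      - "\\btsh\\b(?: de)?\\s*[:]?\\s*(?P<value>\\d+(?:[.,]\\d+)?)\\s*(?P<unit>mui/l|uui/ml)?"
  - variable_id: potassium
    value_type: numeric
    variable_class: lab
    target_sections: [ComplementaryTests]
    canonical_unit: "mmol/l"
    unit_factors: {"mmol/l": 1.0, "meq/l": 1.0}
    patterns:
      - "(?:potasio|\\bk\\b)(?: de)?\\s*[:]?\\s*(?P<value>\\d+(?:[.,]\\d+)?)\\s*(?P<unit>mmol/l|meq/l)?"
  - variable_id: glucose
    value_type: numeric
    variable_class: lab
    target_sections: [ComplementaryTests]
    canonical_unit: "mg/dl"
    unit_factors: {"mg/dl": 1.0}
    patterns:
      - "(?:glucosa|glucemia)(?: basal)?(?: de)?\\s*[:]?\\s*(?P<value>\\d+(?:[.,]\\d+)?)\\s*(?P<unit>mg/dl)?"
  - variable_id: lvef
    value_type: numeric
    variable_class: echo
    target_sections: [ComplementaryTests]
    canonical_unit: "%"
    unit_factors: {"%": 1.0}
    patterns:
      - "(?:\\bfevi\\b|fraccion de eyeccion)(?: del| de)?\\s*[:]?\\s*(?P<value>\\d+(?:[.,]\\d+)?)\\s*(?P<unit>%)?"
  - variable_id: la_diameter
    value_type: numeric
    variable_class: echo
    target_sections: [ComplementaryTests]
    canonical_unit: "mm"
    unit_factors: {"mm": 1.0}
    patterns:
      - "(?:auricula izquierda|\\bai\\b)(?: de)?\\s*[:]?\\s*(?P<value>\\d+(?:[.,]\\d+)?)\\s*(?P<unit>mm)"
  - variable_id: anticoagulant
    value_type: medication
    variable_class: medication
    target_sections: [Treatment]
    patterns:
      - "\\b(?:apixaban|rivaroxaban|edoxaban|dabigatran|acenocumarol|warfarina)\\b"
    atc_map:
      apixaban: B01AF02
      rivaroxaban: B01AF01
      edoxaban: B01AF03
      dabigatran: B01AE07
      acenocumarol: B01AA07
      warfarina: B01AA03
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
      - "\\b(?:amiodarona|flecainida|dronedarona)\\b"
    atc_map:
      amiodarona: C01BD01
      flecainida: C01BC04
      dronedarona: C01BD07
  - variable_id: cardioversion
    value_type: boolean
    variable_class: procedure
    target_sections: [Evolution, CurrentIllness]
    patterns: ["cardioversion"]
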
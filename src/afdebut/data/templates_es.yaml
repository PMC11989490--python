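# Spanish sentence templates for the synthetic discharge-report generator.
# First entry of each list is the "primary" form; later entries are the
# synonym variants selected under synonym noise. Numeric templates may carry
# unit_factor/decimals to render the canonical value in an alternate unit.
headings:
  Header: ["DATOS DEL EPISODIO", "CABECERA"]
  ReasonForConsultation: ["MOTIVO DE CONSULTA", "MOTIVO DE INGRESO"]
  PersonalHistory: ["ANTECEDENTES PERSONALES", "ANTECEDENTES"]
  CurrentIllness: ["ENFERMEDAD ACTUAL", "HISTORIA ACTUAL"]
  GeneralExploration: ["EXPLORACIÓN GENERAL", "EXPLORACIÓN FÍSICA"]
  ComplementaryTests: ["PRUEBAS COMPLEMENTARIAS", "EXPLORACIONES COMPLEMENTARIAS"]
  Diagnosis: ["DIAGNÓSTICO", "JUICIO CLÍNICO"]
  Treatment: ["TRATAMIENTO", "TRATAMIENTO AL ALTA"]
  Evolution: ["EVOLUCIÓN", "EVOLUCIÓN CLÍNICA"]
filler:
  Header:
    - "Servicio de Cardiología. Informe de alta."
    - "NHC: {patient_id}."
    - "Fecha de alta: {date}."
  ReasonForConsultation:
    - "Palpitaciones."
    - "Disnea de esfuerzo."
    - "Dolor torácico."
  CurrentIllness:
    - "Paciente que acude por clínica de varias horas de evolución."
    - "Refiere malestar general de inicio brusco."
  GeneralExploration:
    - "Consciente y orientado. Buen estado general."
    - "TA 128/76 mmHg. Afebril."
  ComplementaryTests:
    - "Radiografía de tórax sin alteraciones."
  Evolution:
    - "Buena evolución clínica durante el ingreso."
    - "Permanece estable y asintomático al alta."
  Treatment:
    - "Dieta hiposódica."
    - "Control por su médico de atención primaria."
diagnosis_negative:
  - "Dolor torácico atípico."
  - "Bronquitis aguda."
  - "Síncope vasovagal."
  - "Gastroenteritis aguda."
  - "Lumbalgia mecánica."
  - "Neumonía adquirida en la comunidad."
af:
  onset_qualified:
    - "Fibrilación auricular de novo."
    - "Primer episodio de fibrilación auricular."
    - "Debut de fibrilación auricular."
  onset_bare:
    - "Fibrilación auricular."
  prior:
    - "Fibrilación auricular conocida."
    - "FA paroxística conocida."
    - "Fibrilación auricular permanente."
  negated:
    - "No fibrilación auricular."
    - "Sin evidencia de fibrilación auricular."
  ecg:
    - "ECG: fibrilación auricular con respuesta ventricular rápida."
  ecg_normal:
    - "ECG: ritmo sinusal."
variables:
  age:
    section: ReasonForConsultation
    affirm:
      - {text: "Paciente de {value} años.", decimals: 0}
      - {text: "Edad: {value} años.", decimals: 0}
  sex:
    section: ReasonForConsultation
    affirm:
      - {text: "Sexo: varón.", value: male}
      - {text: "Paciente varón.", value: male}
      - {text: "Sexo: mujer.", value: female}
      - {text: "Paciente mujer.", value: female}
  diabetes:
    section: PersonalHistory
    affirm:
      - "Diabetes mellitus tipo 2."
      - "DM tipo 2 en tratamiento dietético."
    negated:
      - "No diabetes."
      - "Niega diabetes."
  hypertension:
    section: PersonalHistory
    affirm:
      - "Hipertensión arterial en tratamiento."
      - "HTA de larga evolución."
    negated:
      - "No hipertensión arterial."
      - "Sin hipertensión conocida."
  heart_failure:
    section: PersonalHistory
    affirm:
      - "Insuficiencia cardíaca crónica."
      - "ICC estable."
    negated:
      - "No insuficiencia cardíaca."
      - "Niega insuficiencia cardíaca."
  copd:
    section: PersonalHistory
    affirm:
      - "EPOC moderado."
      - "Enfermedad pulmonar obstructiva crónica."
    negated:
      - "No EPOC."
  stroke:
    section: PersonalHistory
    affirm:
      - "Ictus isquémico previo."
      - "ACV antiguo."
    negated:
      - "No ictus previos."
      - "Niega accidente cerebrovascular."
  ckd:
    section: PersonalHistory
    affirm:
      - "Enfermedad renal crónica estadio 3."
      - "ERC conocida."
    negated:
      - "No enfermedad renal crónica."
  hyperthyroidism:
    section: PersonalHistory
    affirm:
      - "Hipertiroidismo en tratamiento."
    negated:
      - "No hipertiroidismo."
      - "Hipertiroidismo descartado."
  sleep_apnea:
    section: PersonalHistory
    affirm:
      - "SAOS con CPAP nocturna."
      - "Apnea obstructiva del sueño."
    negated:
      - "No SAOS."
  creatinine:
    section: ComplementaryTests
    affirm:
      - {text: "Creatinina {value} mg/dl.", unit_factor: 1.0, decimals: 2}
      - {text: "Creatinina sérica de {value} mg/dl.", unit_factor: 1.0, decimals: 2}
      - {text: "Creatinina {value} umol/l.", unit_factor: 88.4, decimals: 0}
  hemoglobin:
    section: ComplementaryTests
    affirm:
      - {text: "Hemoglobina {value} g/dl.", unit_factor: 1.0, decimals: 1}
      - {text: "Hb {value} g/dl.", unit_factor: 1.0, decimals: 1}
  tsh:
    section: ComplementaryTests
    affirm:
      - {text: "TSH {value} mUI/l.", unit_factor: 1.0, decimals: 2}
      - {text: "TSH de {value} uUI/ml.", unit_factor: 1.0, decimals: 2}
  potassium:
    section: ComplementaryTests
    affirm:
      - {text: "Potasio {value} mmol/l.", unit_factor: 1.0, decimals: 1}
      - {text: "K {value} mEq/l.", unit_factor: 1.0, decimals: 1}
  glucose:
    section: ComplementaryTests
    affirm:
      - {text: "Glucosa {value} mg/dl.", unit_factor: 1.0, decimals: 0}
      - {text: "Glucemia basal de {value} mg/dl.", unit_factor: 1.0, decimals: 0}
  lvef:
    section: ComplementaryTests
    affirm:
      - {text: "FEVI {value}%.", unit_factor: 1.0, decimals: 0}
      - {text: "Fracción de eyección del {value}%.", unit_factor: 1.0, decimals: 0}
  la_diameter:
    section: ComplementaryTests
    affirm:
      - {text: "Aurícula izquierda de {value} mm.", unit_factor: 1.0, decimals: 0}
      - {text: "AI {value} mm.", unit_factor: 1.0, decimals: 0}
  anticoagulant:
    section: Treatment
    affirm:
      - "{drug} {dose}."
      - "Se pauta {drug} {dose}."
    options:
      - {display: "Apixabán", atc: B01AF02, dose: "5 mg cada 12 horas"}
      - {display: "Rivaroxabán", atc: B01AF01, dose: "20 mg cada 24 horas"}
      - {display: "Edoxabán", atc: B01AF03, dose: "60 mg cada 24 horas"}
      - {display: "Dabigatrán", atc: B01AE07, dose: "110 mg cada 12 horas"}
      - {display: "Acenocumarol", atc: B01AA07, dose: "según pauta de hematología"}
      - {display: "Warfarina", atc: B01AA03, dose: "según pauta"}
  beta_blocker:
    section: Treatment
    affirm:
      - "{drug} {dose}."
      - "Se pauta {drug} {dose}."
    options:
      - {display: "Bisoprolol", atc: C07AB07, dose: "2.5 mg cada 24 horas"}
      - {display: "Atenolol", atc: C07AB03, dose: "50 mg cada 24 horas"}
      - {display: "Carvedilol", atc: C07AG02, dose: "6.25 mg cada 12 horas"}
      - {display: "Metoprolol", atc: C07AB02, dose: "50 mg cada 12 horas"}
  antiarrhythmic:
    section: Treatment
    affirm:
      - "{drug} {dose}."
      - "Se pauta {drug} {dose}."
    options:
      - {display: "Amiodarona", atc: C01BD01, dose: "200 mg cada 24 horas"}
      - {display: "Flecainida", atc: C01BC04, dose: "100 mg cada 12 horas"}
      - {display: "Dronedarona", atc: C01BD07, dose: "400 mg cada 12 horas"}
  cardioversion:
    section: Evolution
    affirm:
      - "Se realizó cardioversión eléctrica efectiva."
      - "Cardioversión farmacológica con paso a ritmo sinusal."
    negated:
      - "No se realizó cardioversión."
distractors:
  Evolution:
    - "Creatinina previa de 1.4 mg/dl en informe externo."
    - "Pendiente de control analítico ambulatorio de hemoglobina."
  Treatment:
    - "Vitaminol 10 mg cada 24 horas."
  PersonalHistory:
    - "Madre con cardiopatía isquémica."
  Diagnosis:
    - "Flutter auricular típico."
  GeneralExploration:
    - "Soplo sistólico II/VI conocido."
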
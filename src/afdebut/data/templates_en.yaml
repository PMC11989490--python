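# English sentence templates for the synthetic discharge-report generator.
headings:
  Header: ["EPISODE DETAILS", "HEADER"]
  ReasonForConsultation: ["REASON FOR CONSULTATION", "REASON FOR ADMISSION"]
  PersonalHistory: ["PERSONAL HISTORY", "PAST MEDICAL HISTORY"]
  CurrentIllness: ["CURRENT ILLNESS", "HISTORY OF PRESENT ILLNESS"]
  GeneralExploration: ["GENERAL EXPLORATION", "PHYSICAL EXAMINATION"]
  ComplementaryTests: ["COMPLEMENTARY TESTS", "INVESTIGATIONS"]
  Diagnosis: ["DIAGNOSIS", "CLINICAL IMPRESSION"]
  Treatment: ["TREATMENT", "TREATMENT AT DISCHARGE"]
  Evolution: ["EVOLUTION", "CLINICAL COURSE"]
filler:
  Header:
    - "Cardiology Department. Discharge report."
    - "Record number: {patient_id}."
    - "Discharge date: {date}."
  ReasonForConsultation:
    - "Palpitations."
    - "Exertional dyspnea."
    - "Chest discomfort."
  CurrentIllness:
    - "Symptoms started several hours before admission."
    - "Reports sudden-onset general discomfort."
  GeneralExploration:
    - "Alert and oriented. Good general condition."
    - "BP 128/76 mmHg. Afebrile."
  ComplementaryTests:
    - "Chest X-ray unremarkable."
  Evolution:
    - "Good clinical course during admission."
    - "Stable and asymptomatic at discharge."
  Treatment:
    - "Low-salt diet."
    - "Follow-up with primary care physician."
diagnosis_negative:
  - "Atypical chest pain."
  - "Acute bronchitis."
  - "Vasovagal syncope."
  - "Acute gastroenteritis."
  - "Mechanical low back pain."
  - "Community-acquired pneumonia."
af:
  onset_qualified:
    - "New-onset atrial fibrillation."
    - "First episode of atrial fibrillation."
    - "De novo atrial fibrillation."
  onset_bare:
    - "Atrial fibrillation."
  prior:
    - "Known atrial fibrillation."
    - "Paroxysmal atrial fibrillation."
    - "Permanent atrial fibrillation on treatment."
  negated:
    - "No atrial fibrillation."
    - "No evidence of atrial fibrillation."
  ecg:
    - "ECG: atrial fibrillation with rapid ventricular response."
  ecg_normal:
    - "ECG: sinus rhythm."
variables:
  age:
    section: ReasonForConsultation
    affirm:
      - {text: "Patient aged {value} years.", decimals: 0}
      - {text: "Age: {value} years.", decimals: 0}
  sex:
    section: ReasonForConsultation
    affirm:
      - {text: "Sex: male.", value: male}
      - {text: "Male patient.", value: male}
      - {text: "Sex: female.", value: female}
      - {text: "Female patient.", value: female}
  diabetes:
    section: PersonalHistory
    affirm:
      - "Type 2 diabetes mellitus."
      - "DM type 2 on diet."
    negated:
      - "No diabetes."
      - "Denies diabetes."
  hypertension:
    section: PersonalHistory
    affirm:
      - "Arterial hypertension on treatment."
      - "Long-standing HTN."
    negated:
      - "No hypertension."
      - "Denies hypertension."
  heart_failure:
    section: PersonalHistory
    affirm:
      - "Chronic heart failure."
      - "Stable CHF."
    negated:
      - "No heart failure."
  copd:
    section: PersonalHistory
    affirm:
      - "Moderate COPD."
      - "Chronic obstructive pulmonary disease."
    negated:
      - "No COPD."
  stroke:
    section: PersonalHistory
    affirm:
      - "Previous ischemic stroke."
      - "Old CVA."
    negated:
      - "No previous stroke."
      - "Denies stroke."
  ckd:
    section: PersonalHistory
    affirm:
      - "Chronic kidney disease stage 3."
      - "Known CKD."
    negated:
      - "No chronic kidney disease."
  hyperthyroidism:
    section: PersonalHistory
    affirm:
      - "Hyperthyroidism on treatment."
    negated:
      - "No hyperthyroidism."
      - "Hyperthyroidism ruled out."
  sleep_apnea:
    section: PersonalHistory
    affirm:
      - "Obstructive sleep apnea on CPAP."
      - "OSA on nocturnal CPAP."
    negated:
      - "No sleep apnea."
  creatinine:
    section: ComplementaryTests
    affirm:
      - {text: "Creatinine {value} mg/dl.", unit_factor: 1.0, decimals: 2}
      - {text: "Serum creatinine of {value} mg/dl.", unit_factor: 1.0, decimals: 2}
      - {text: "Creatinine {value} umol/l.", unit_factor: 88.4, decimals: 0}
  hemoglobin:
    section: ComplementaryTests
    affirm:
      - {text: "Hemoglobin {value} g/dl.", unit_factor: 1.0, decimals: 1}
      - {text: "Hb {value} g/dl.", unit_factor: 1.0, decimals: 1}
  tsh:
    section: ComplementaryTests
    affirm:
      - {text: "TSH {value} mUI/l.", unit_factor: 1.0, decimals: 2}
      - {text: "TSH of {value} uUI/ml.", unit_factor: 1.0, decimals: 2}
  potassium:
    section: ComplementaryTests
    affirm:
      - {text: "Potassium {value} mmol/l.", unit_factor: 1.0, decimals: 1}
      - {text: "K {value} mEq/l.", unit_factor: 1.0, decimals: 1}
  glucose:
    section: ComplementaryTests
    affirm:
      - {text: "Glucose {value} mg/dl.", unit_factor: 1.0, decimals: 0}
      - {text: "Fasting glucose of {value} mg/dl.", unit_factor: 1.0, decimals: 0}
  lvef:
    section: ComplementaryTests
    affirm:
      - {text: "LVEF {value}%.", unit_factor: 1.0, decimals: 0}
      - {text: "Ejection fraction of {value}%.", unit_factor: 1.0, decimals: 0}
  la_diameter:
    section: ComplementaryTests
    affirm:
      - {text: "Left atrium of {value} mm.", unit_factor: 1.0, decimals: 0}
      - {text: "LA {value} mm.", unit_factor: 1.0, decimals: 0}
  anticoagulant:
    section: Treatment
    affirm:
      - "{drug} {dose}."
      - "Started on {drug} {dose}."
    options:
      - {display: "Apixaban", atc: B01AF02, dose: "5 mg twice daily"}
      - {display: "Rivaroxaban", atc: B01AF01, dose: "20 mg once daily"}
      - {display: "Edoxaban", atc: B01AF03, dose: "60 mg once daily"}
      - {display: "Dabigatran", atc: B01AE07, dose: "110 mg twice daily"}
      - {display: "Acenocoumarol", atc: B01AA07, dose: "per anticoagulation clinic"}
      - {display: "Warfarin", atc: B01AA03, dose: "per INR"}
  beta_blocker:
    section: Treatment
    affirm:
      - "{drug} {dose}."
      - "Started on {drug} {dose}."
    options:
      - {display: "Bisoprolol", atc: C07AB07, dose: "2.5 mg once daily"}
      - {display: "Atenolol", atc: C07AB03, dose: "50 mg once daily"}
      - {display: "Carvedilol", atc: C07AG02, dose: "6.25 mg twice daily"}
      - {display: "Metoprolol", atc: C07AB02, dose: "50 mg twice daily"}
  antiarrhythmic:
    section: Treatment
    affirm:
      - "{drug} {dose}."
      - "Started on {drug} {dose}."
    options:
      - {display: "Amiodarone", atc: C01BD01, dose: "200 mg once daily"}
      - {display: "Flecainide", atc: C01BC04, dose: "100 mg twice daily"}
      - {display: "Dronedarone", atc: C01BD07, dose: "400 mg twice daily"}
  cardioversion:
    section: Evolution
    affirm:
      - "Effective electrical cardioversion performed."
      - "Pharmacological cardioversion with return to sinus rhythm."
    negated:
      - "No cardioversion was performed."
distractors:
  Evolution:
    - "Previous creatinine of 1.4 mg/dl in an outside report."
    - "Outpatient hemoglobin control pending."
  Treatment:
    - "Vitaminol 10 mg once daily."
  PersonalHistory:
    - "Mother with ischemic heart disease."
  Diagnosis:
    - "Typical atrial flutter."
  GeneralExploration:
    - "Known II/VI systolic murmur."
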
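# Default 25-variable prognostic network topology.
#
# States are ordered from LOW risk to HIGH risk (curated per clinical
# direction, e.g. "R0 Resection: Yes" is low-risk, "Albumin: Low" is
# high-risk).  Pre-operative variables build the pre-operative model;
# post-operative variables are added for prognostic updating.
variables:
  # ---- pre-operative -------------------------------------------------
  - name: mGPS
    states: ["0", "1", "2"]
    phase: pre_operative
    group: Inflammatory Markers
  - name: Neutrophil Lymphocyte Ratio
    states: ["<5", ">5"]
    phase: pre_operative
    group: Inflammatory Markers
  - name: Albumin
    states: ["Normal", "Low"]
    phase: pre_operative
    group: Inflammatory Markers
  - name: Pre-treatment Ca19-9
    states: ["<50", "50-999", ">1000"]
    phase: pre_operative
    group: Tumour Markers
  - name: CEA
    states: ["<5", ">5"]
    phase: pre_operative
    group: Tumour Markers
  - name: Tumour Size
    states: ["<2cm", ">2cm"]
    phase: pre_operative
    group: Tumour Factors
  - name: Tumour Location
    states: ["HOP", "Body/Tail"]
    phase: pre_operative
    group: Tumour Factors
  - name: T Stage
    states: ["T1", "T2", "T3", "T4"]
    phase: pre_operative
    group: Tumour Factors
  - name: Jaundice
    states: ["No", "Yes"]
    phase: pre_operative
    group: Tumour Factors
  - name: Age
    states: ["<70", ">70"]
    phase: pre_operative
    group: Patient Factors
  - name: Performance Status
    states: ["Good", "Moderate", "Poor"]
    phase: pre_operative
    group: Patient Factors
  - name: Diabetes
    states: ["No", "Yes"]
    phase: pre_operative
    group: Patient Factors
  - name: Smoking
    states: ["Non-smoker", "Smoker"]
    phase: pre_operative
    group: Patient Factors
  - name: BMI
    states: ["Normal", "Low"]
    phase: pre_operative
    group: Patient Factors
  - name: Pre-operative Blood Transfusion
    states: ["No", "Yes"]
    phase: pre_operative
    group: Patient Factors
  - name: Response to Neoadjuvant Treatment
    states: ["Stable", "Progression/Unresectable"]
    phase: pre_operative
    group: Neoadjuvant Response
  # ---- post-operative ------------------------------------------------
  - name: Lymph Node Positive
    states: ["No", "Yes"]
    phase: post_operative
    group: Pathology
  - name: Lymph Node Ratio
    states: ["<0.3", ">0.3"]
    phase: post_operative
    group: Pathology
  - name: Tumour Grade
    states: ["G1/G2", "G3/G4"]
    phase: post_operative
    group: Pathology
  - name: R0 Resection
    states: ["Yes", "No"]
    phase: post_operative
    group: Pathology
  - name: AJCC Stage
    states: ["0", "1", "2", "3", "4"]
    phase: post_operative
    group: Pathology
  - name: Vascular Involvement
    states: ["No", "Yes"]
    phase: post_operative
    group: Pathology
  - name: Perineural Invasion
    states: ["No", "Yes"]
    phase: post_operative
    group: Pathology
  - name: Post-treatment Ca19-9
    states: ["<120", ">120"]
    phase: post_operative
    group: Pathology
  - name: Adjuvant Therapy
    states: ["Yes", "No"]
    phase: post_operative
    group: Adjuvant  # category node named apart from its single member variable
output_name: Poor Prognosis
output_states: ["no", "yes"]
n_group_states: 5
threshold: 0.5
variance_rule: inverse-weight-sum
base_variance: 0.05
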
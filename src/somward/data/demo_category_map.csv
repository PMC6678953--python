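prefix,label
I25,atherosclerotic_heart_disease
I21,myocardial_infarction
I22,myocardial_infarction
I50,heart_failure
I11,hypertensive_heart_disease
I10,hypertension
I46,cardiac_arrest
I60,unspecified_stroke
I61,unspecified_stroke
I62,unspecified_stroke
I63,unspecified_stroke
I64,unspecified_stroke
J44,copd
J96,respiratory_failure
J12,pneumonia
J13,pneumonia
J14,pneumonia
J15,pneumonia
J16,pneumonia
J17,pneumonia
J18,pneumonia
J09,influenza
J10,influenza
J11,influenza
J69,pneumonitis
F17,nicotine_dependence
F01,dementia
F03,dementia
G30,alzheimer_disease
G20,parkinson_disease
A40,other_sepsis
A41,other_sepsis
E10,diabetes_mellitus
E11,diabetes_mellitus
E12,diabetes_mellitus
E13,diabetes_mellitus
E14,diabetes_mellitus
E66,obesity
N19,unspecified_kidney_failure
N18,chronic_kidney_disease
N39,urinary_tract_infection
C50,breast_cancer
C61,prostate_cancer
C34,lung_cancer
C18,colorectal_cancer
C19,colorectal_cancer
C20,colorectal_cancer
C15,gastrointestinal_cancer
C16,gastrointestinal_cancer
C17,gastrointestinal_cancer
C21,gastrointestinal_cancer
C22,gastrointestinal_cancer
C23,gastrointestinal_cancer
C24,gastrointestinal_cancer
C25,gastrointestinal_cancer
C26,gastrointestinal_cancer
C82,non_hodgkin_lymphoma
C83,non_hodgkin_lymphoma
C84,non_hodgkin_lymphoma
C85,non_hodgkin_lymphoma
K70,alcoholic_liver_disease
K74,liver_fibrosis_cirrhosis
T40,drug_poisoning
X40,drug_poisoning
X41,drug_poisoning
X42,drug_poisoning
X43,drug_poisoning
X44,drug_poisoning
T51,alcohol_poisoning
X45,alcohol_poisoning
T14,open_wound
T71,suffocation
C,other_cancer
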
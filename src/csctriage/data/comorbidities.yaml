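# Default comorbidity catalog for longer-term-mortality points.
# tier: five_year  -> comorbidity expected to reduce 5-year survival (2 points)
# tier: one_year   -> comorbidity expected to reduce 1-year survival (4 points)
five_year:
  moderate_dementia: Moderate dementia
  malignancy_lt10y_survival: Malignancy with less than 10-year expected survival
  nyha_class_iii_heart_failure: New York Heart Association class III heart failure
  moderate_lung_disease: Moderate lung disease
  end_stage_kidney_disease: End-stage kidney disease
  severe_inoperable_cad: Severe (inoperable) coronary artery disease
one_year:
  severe_dementia: Severe dementia
  metastatic_stage_iv_cancer: Metastatic or stage IV cancer
  nyha_class_iv_heart_failure: New York Heart Association class IV heart failure
  severe_lung_disease: Severe lung disease
  cirrhosis_meld_gt20: Cirrhosis with MELD score greater than 20
  tbi_gcs_motor_1: Traumatic brain injury with best GCS motor response of 1
  severe_burns: Severe burns
  cardiac_arrest: Cardiac arrest (unwitnessed, recurrent, or trauma-related)
  severe_immunocompromise: Severe immunocompromised state
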
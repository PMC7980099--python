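# SOFA subscore cut-points (Vincent et al. 1996 consensus definition).
# Each organ system lists the thresholds for subscores 1..4; a value that
# crosses no threshold scores 0.  Edit this file to swap SOFA dialects.
respiration:
  # PaO2/FiO2 (mmHg), upper-inclusive; subscores 3-4 additionally require
  # respiratory support
  pao2_fio2_upper_inclusive: {1: 400, 2: 300, 3: 200, 4: 100}
  support_required_from: 3
coagulation:
  # platelets, 10^3/uL, upper-inclusive
  platelets_upper_inclusive: {1: 150, 2: 100, 3: 50, 4: 20}
liver:
  # bilirubin, mg/dL
  bilirubin_lower_inclusive: {1: 1.2, 2: 2.0, 3: 6.0, 4: 12.0}
cardiovascular:
  # MAP < threshold scores 1; vasopressor categories score 2-4 directly
  map_upper_exclusive: 70
  vasopressor_scores:
    none: 0
    dopamine_le5_or_dobutamine: 2
    dopamine_gt5_or_epi_le01_or_norepi_le01: 3
    dopamine_gt15_or_epi_gt01_or_norepi_gt01: 4
cns:
  # Glasgow Coma Scale; lower is worse
  gcs_upper_inclusive: {1: 14, 2: 12, 3: 9, 4: 5}
renal:
  # creatinine, mg/dL (lower-inclusive) or urine output, mL/day (upper-exclusive)
  creatinine_lower_inclusive: {1: 1.2, 2: 2.0, 3: 3.5, 4: 5.0}
  urine_upper_exclusive: {3: 500, 4: 200}
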
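# Default SOFA-2 rule set.
#
# The numeric cut-points below are an editable transcription of the SOFA-2
# structure (revised oxygenation bands with an SpO2/FiO2 fallback,
# support-gated top respiratory bands, graduated MAP bands without
# vasopressors, agent-count vasopressor tiers, RRT/MCS maxima, delirium
# floor, revised bilirubin/platelet bands).  Sites holding the
# authoritative threshold supplement should edit this file; the engine
# treats it purely as data.  Every band declares its own edge inclusivity.

window_hours: 24
sf_fallback_spo2_max: 98          # SpO2 readings >= 98% never enter S/F
pf_staleness_hours: 4             # FiO2 carried forward at most 4 h
vasopressor_min_minutes: 60
infusion_merge_gap_minutes: 15

vasopressor_drugs:
  - norepinephrine
  - epinephrine
  - dopamine
  - dobutamine
  - vasopressin
  - phenylephrine
  - milrinone
  - angiotensin II

delirium_agents:
  - dexmedetomidine
  - haloperidol
  - quetiapine
  - ziprasidone
  - olanzapine
delirium_floor: 1

rrt_max_score: 4
mcs_max_score: 4
missing_component_score: 0

advanced_resp_modalities: [IMV, NIV, CPAP, BiPAP, HFNC, ECMO]
respiratory_unsupported_cap: 2

respiratory_pf_bands:             # PaO2/FiO2, mmHg
  - {score: 0, lower: 400, lower_inclusive: true,  label: "P/F >= 400"}
  - {score: 1, lower: 300, upper: 400, lower_inclusive: true, upper_inclusive: false, label: "P/F 300-399"}
  - {score: 2, lower: 200, upper: 300, lower_inclusive: true, upper_inclusive: false, label: "P/F 200-299"}
  - {score: 3, lower: 100, upper: 200, lower_inclusive: true, upper_inclusive: false, requires_support: true, label: "P/F 100-199 on advanced support"}
  - {score: 4, upper: 100, upper_inclusive: false, requires_support: true, label: "P/F < 100 on advanced support"}

respiratory_sf_bands:             # SpO2/FiO2, only SpO2 < 98%
  - {score: 0, lower: 370, lower_inclusive: true,  label: "S/F >= 370"}
  - {score: 1, lower: 300, upper: 370, lower_inclusive: true, upper_inclusive: false, label: "S/F 300-369"}
  - {score: 2, lower: 200, upper: 300, lower_inclusive: true, upper_inclusive: false, label: "S/F 200-299"}
  - {score: 3, lower: 120, upper: 200, lower_inclusive: true, upper_inclusive: false, requires_support: true, label: "S/F 120-199 on advanced support"}
  - {score: 4, upper: 120, upper_inclusive: false, requires_support: true, label: "S/F < 120 on advanced support"}

map_bands:                        # mean arterial pressure, mmHg (no vasopressors)
  - {score: 0, lower: 70, lower_inclusive: true, label: "MAP >= 70"}
  - {score: 1, lower: 60, upper: 70, lower_inclusive: true, upper_inclusive: false, label: "MAP 60-69"}
  - {score: 2, lower: 50, upper: 60, lower_inclusive: true, upper_inclusive: false, label: "MAP 50-59"}
  - {score: 3, lower: 40, upper: 50, lower_inclusive: true, upper_inclusive: false, label: "MAP 40-49"}
  - {score: 4, upper: 40, upper_inclusive: false, label: "MAP < 40"}

vasopressor_tiers:                # distinct qualifying agents -> subscore
  1: 2
  2: 3
  3: 4

gcs_bands:                        # GCS total, 3-15
  - {score: 0, lower: 15, lower_inclusive: true, label: "GCS 15"}
  - {score: 1, lower: 13, upper: 15, lower_inclusive: true, upper_inclusive: false, label: "GCS 13-14"}
  - {score: 2, lower: 10, upper: 13, lower_inclusive: true, upper_inclusive: false, label: "GCS 10-12"}
  - {score: 3, lower: 6,  upper: 10, lower_inclusive: true, upper_inclusive: false, label: "GCS 6-9"}
  - {score: 4, upper: 6,  upper_inclusive: false, label: "GCS 3-5"}

gcs_motor_bands:                  # GCS motor, 1-6 (fallback when total absent)
  - {score: 0, lower: 6, lower_inclusive: true, label: "motor 6"}
  - {score: 1, lower: 5, upper: 6, lower_inclusive: true, upper_inclusive: false, label: "motor 5"}
  - {score: 2, lower: 4, upper: 5, lower_inclusive: true, upper_inclusive: false, label: "motor 4"}
  - {score: 3, lower: 2, upper: 4, lower_inclusive: true, upper_inclusive: false, label: "motor 2-3"}
  - {score: 4, upper: 2, upper_inclusive: false, label: "motor 1"}

bilirubin_bands:                  # mg/dL (higher is worse)
  - {score: 0, upper: 1.2, upper_inclusive: false, label: "bilirubin < 1.2"}
  - {score: 1, lower: 1.2, upper: 2.0, lower_inclusive: true, upper_inclusive: false, label: "bilirubin 1.2-1.9"}
  - {score: 2, lower: 2.0, upper: 6.0, lower_inclusive: true, upper_inclusive: false, label: "bilirubin 2.0-5.9"}
  - {score: 3, lower: 6.0, upper: 12.0, lower_inclusive: true, upper_inclusive: false, label: "bilirubin 6.0-11.9"}
  - {score: 4, lower: 12.0, lower_inclusive: true, label: "bilirubin >= 12"}

creatinine_bands:                 # mg/dL (higher is worse)
  - {score: 0, upper: 1.2, upper_inclusive: false, label: "creatinine < 1.2"}
  - {score: 1, lower: 1.2, upper: 2.0, lower_inclusive: true, upper_inclusive: false, label: "creatinine 1.2-1.9"}
  - {score: 2, lower: 2.0, upper: 3.5, lower_inclusive: true, upper_inclusive: false, label: "creatinine 2.0-3.4"}
  - {score: 3, lower: 3.5, upper: 5.0, lower_inclusive: true, upper_inclusive: false, label: "creatinine 3.5-4.9"}
  - {score: 4, lower: 5.0, lower_inclusive: true, label: "creatinine >= 5"}

urine_bands:                      # total mL over the window (lower is worse)
  - {score: 0, lower: 500, lower_inclusive: true, label: "urine >= 500 mL/24h"}
  - {score: 3, lower: 200, upper: 500, lower_inclusive: true, upper_inclusive: false, label: "urine 200-499 mL/24h"}
  - {score: 4, upper: 200, upper_inclusive: false, label: "urine < 200 mL/24h"}

platelet_bands:                   # x10^3/uL (lower is worse)
  - {score: 0, lower: 150, lower_inclusive: true, label: "platelets >= 150"}
  - {score: 1, lower: 100, upper: 150, lower_inclusive: true, upper_inclusive: false, label: "platelets 100-149"}
  - {score: 2, lower: 50, upper: 100, lower_inclusive: true, upper_inclusive: false, label: "platelets 50-99"}
  - {score: 3, lower: 20, upper: 50, lower_inclusive: true, upper_inclusive: false, label: "platelets 20-49"}
  - {score: 4, upper: 20, upper_inclusive: false, label: "platelets < 20"}
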
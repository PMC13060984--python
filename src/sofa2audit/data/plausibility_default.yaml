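# Plausibility bounds on per-stay worst values.  Stays with any worst value
# outside its [min, max] range are excluded from the analytic cohort.
#
# These are permissive artifact defaults, not the validation study's
# unpublished supplement; sites holding the authoritative ranges should
# override this file.
map_min:        {min: 10,   max: 250}    # mmHg
gcs_total_min:  {min: 3,    max: 15}
gcs_motor_min:  {min: 1,    max: 6}
pf_min:         {min: 20,   max: 800}    # mmHg ratio
sf_min:         {min: 40,   max: 500}
bilirubin_max:  {min: 0.05, max: 80}     # mg/dL
creatinine_max: {min: 0.1,  max: 40}     # mg/dL
urine_total:    {min: 0,    max: 30000}  # mL / 24 h
platelets_min:  {min: 1,    max: 2500}   # x10^3/uL
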
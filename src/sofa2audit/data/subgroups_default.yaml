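# Demographic subgroup scheme: raw-label vocabularies (MIMIC-style) mapped
# to the analysis categories, age-band edges, and reference levels.
# Matching is case-insensitive on stripped labels; unmapped labels fall to
# the dimension's default with a warning counter.

age_bins: [18, 45, 65, 75]        # left-closed bands: 18-44, 45-64, 65-74, 75+

sex_map:
  M: Male
  MALE: Male
  F: Female
  FEMALE: Female
sex_default: Unknown

hispanic_precedence: true          # any raw label containing HISPANIC -> Hispanic
race_map:
  WHITE: White
  WHITE - RUSSIAN: White
  WHITE - OTHER EUROPEAN: White
  WHITE - BRAZILIAN: White
  WHITE - EASTERN EUROPEAN: White
  PORTUGUESE: White
  BLACK: Black
  BLACK/AFRICAN AMERICAN: Black
  BLACK/AFRICAN: Black
  BLACK/CAPE VERDEAN: Black
  BLACK/CARIBBEAN ISLAND: Black
  HISPANIC: Hispanic
  HISPANIC OR LATINO: Hispanic
  HISPANIC/LATINO: Hispanic
  SOUTH AMERICAN: Hispanic
  ASIAN: Asian
  ASIAN - CHINESE: Asian
  ASIAN - SOUTH EAST ASIAN: Asian
  ASIAN - ASIAN INDIAN: Asian
  ASIAN - KOREAN: Asian
  NATIVE HAWAIIAN OR OTHER PACIFIC ISLANDER: Other
  AMERICAN INDIAN/ALASKA NATIVE: Other
  MULTIPLE RACE/ETHNICITY: Other
  OTHER: Other
  UNKNOWN: Unknown
  UNABLE TO OBTAIN: Unknown
  PATIENT DECLINED TO ANSWER: Unknown
  PATIENT DECLINED: Unknown
race_default: Other

language_map:
  ENGLISH: English
  "?": Unknown
  UNKNOWN: Unknown
  UNABLE TO OBTAIN: Unknown
  PATIENT DECLINED: Unknown
  NON-ENGLISH: Non-English
language_default: Non-English      # raw labels are specific languages

insurance_map:
  MEDICARE: Medicare
  MEDICAID: Medicaid
  PRIVATE: Private
  COMMERCIAL: Private
  OTHER: Other
  SELF PAY: Other
  GOVERNMENT: Other
  NO CHARGE: Other
insurance_default: Other

reference_levels:
  age_group: "18-44"
  sex: Male
  race_ethnicity: White
  language: English
  insurance: Private
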
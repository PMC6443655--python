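# Claims-based disease definitions: diagnosis codes plus clinically valid
# test codes (any-of).  Procedure-code identifiers of the source claims
# system are not public, so test codes are configurable tokens; replace
# them with real codes when running against real data.

endometriosis:
  diagnosis_codes: [N80]
  # concurrent gynecologic surgery or hormonal prescription
  required_test_codes: [SURG_GYN, RX_GNRH]
  match_level: category

benign_neoplasm_breast:
  diagnosis_codes: [D24]
  # mammography, digital breast tomosynthesis, breast ultrasound
  required_test_codes: [MAMMOGRAPHY, BREAST_TOMO, BREAST_US]
  match_level: category

benign_mammary_dysplasia:
  diagnosis_codes: [N60]
  required_test_codes: [MAMMOGRAPHY, BREAST_TOMO, BREAST_US]
  match_level: category

other_breast_disorders:
  diagnosis_codes: [N64]
  required_test_codes: [MAMMOGRAPHY, BREAST_TOMO, BREAST_US]
  match_level: category

cystitis:
  diagnosis_codes: [N30]
  # urinalysis, microscopic examination, primary culture
  required_test_codes: [URINALYSIS, URINE_MICRO, URINE_CULTURE]
  match_level: category

nontoxic_goitre:
  diagnosis_codes: [E04]
  # TSH, free T3/T4, thyroid antibodies, neck ultrasound
  required_test_codes: [TSH, FREE_T3, FREE_T4, ANTI_TPO, ANTI_TG, NECK_US]
  match_level: category

iron_deficiency_anaemia:
  diagnosis_codes: [D50]
  required_test_codes: [HAEMOGLOBIN]
  match_level: category

other_anaemias:
  diagnosis_codes: [D64]
  required_test_codes: [HAEMOGLOBIN]
  match_level: category
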
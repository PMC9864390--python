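# Default ICD-10 / ATC prefix sets. Conventional stand-ins, editable per study.
cohort:
  ascvd: [I20, I21, I22, I23, I24, I25, I63, I65, I66, I70, I73.9]
  high_cv_risk: [E10, E11]
  hypercholesterolemia: [E78.0, E78.2, E78.4, E78.5]
atc:
  llt: [C10]
  statin: [C10AA, C10BA, C10BX]
  fibrate: [C10AB]
  ezetimibe: [C10AX09]
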
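# Conventional statin intensity banding by daily dose (mg) and lowest
# marketed daily dose per molecule. low_max / moderate_max are inclusive
# upper dose bounds of the low and moderate bands; doses above moderate_max
# are high intensity; a null low_max means the molecule has no low band.
statins:
  simvastatin:    {atc: C10AA01, low_max: 10,   moderate_max: 40, lowest_dose: 10}
  lovastatin:     {atc: C10AA02, low_max: 20,   moderate_max: 40, lowest_dose: 20}
  pravastatin:    {atc: C10AA03, low_max: 20,   moderate_max: 80, lowest_dose: 10}
  fluvastatin:    {atc: C10AA04, low_max: 40,   moderate_max: 80, lowest_dose: 20}
  atorvastatin:   {atc: C10AA05, low_max: null, moderate_max: 20, lowest_dose: 10}
  rosuvastatin:   {atc: C10AA07, low_max: null, moderate_max: 10, lowest_dose: 5}
  pitavastatin:   {atc: C10AA08, low_max: 1,    moderate_max: 4,  lowest_dose: 1}
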
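# Statin-associated muscle symptom (SAMS) ICD-10 codes:
# myalgia, myositis, drug-induced/unspecified myopathy, muscle cramps/spasms.
sams: [M79.1, M60.8, M60.9, G72.0, G72.9, R25.2]
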
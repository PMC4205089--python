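# Laboratory-value and medical-score criteria: analyte/score term + level.
Absolute neutrophil count >={num}/uL
Serum creatinine <={dec} mg/dL
Total bilirubin <={dec} mg/dL
Hemoglobin >={dec} g/dL
Platelet count >={num}/uL
ECOG performance status {lo}-{hi}
Karnofsky performance status >={pct}%
WBC >={num}/mm3
Alkaline phosphatase <={dec} x ULN
DAS28 score >={dec} at screening
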
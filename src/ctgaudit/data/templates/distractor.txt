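# Plain criteria matching no barrier detector.
Histologically confirmed diagnosis of {disease}
Known hypersensitivity to {drug}
Pregnancy or breastfeeding
Current enrollment in another investigational study
Evidence of active uncontrolled infection
Major surgery planned during the study period
Uncontrolled intercurrent illness
Presence of measurable disease on imaging
Documented diagnosis of {disease} by the treating physician
Concomitant treatment with {drug}
History of allergic reactions attributed to {drug}
Life expectancy adequate for study participation
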
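# Lexical sub-population criteria: conditional scoping markers.
If patients are receiving oral corticosteroids, the corticosteroid dose must be stable
If the patient has {condition}, additional cardiac monitoring is required
For patients with {condition}, documented specialist clearance is required
The criteria below only apply to participants enrolled in the expansion cohort
Unless the patient has documented {condition}, antiviral prophylaxis is required
In case of {condition}, enrollment requires approval by the medical monitor
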
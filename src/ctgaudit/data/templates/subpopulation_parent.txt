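# Subgroup headers for the structural sub-population rule; rendered with
# deeper-indented child criteria beneath them.
Patients with {condition}:
Subjects with documented {condition}:
Participants with a history of {condition}:
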
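# Patient behavior/ability criteria: volition or ability phrases.
Patient must be willing to comply with {procedure}
Able to {activity}
Willing to return for all scheduled study visits
Must agree to use adequate contraception during the study
Capable of giving written informed consent
Willingness to undergo {procedure}
Ability to {activity}
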
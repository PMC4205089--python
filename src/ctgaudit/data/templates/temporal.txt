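# Temporally constrained criteria: quantity + time unit + temporal anchor.
# Written to trip the temporal detector and no other category.
At least {n} weeks since prior therapy with {drug}
No more than {n} months since the last dose of {drug}
Diagnosis of {disease} <={n} years
Patients must be taking {drug} for at least {n} months before randomization
Must have completed radiotherapy at least {n} weeks before enrollment
Discontinued {drug} within {n} days before the screening visit
More than {n} weeks since any major surgical procedure
Stable dose of {drug} for at least {n} weeks prior to baseline
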
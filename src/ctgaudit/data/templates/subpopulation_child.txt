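# Child criteria rendered beneath a subgroup header.  Deliberately plain so
# the structural rule, not the child text, carries the sub-population signal.
Must have histologically confirmed organ involvement
Receiving a stable supportive-care regimen
Enrollment requires approval by the medical monitor
Documented stabilization of the underlying disease
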
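# first-degree-relative terms for premature-CAD family history
father
mother
brother
sister
parent
sibling
dad
mom
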
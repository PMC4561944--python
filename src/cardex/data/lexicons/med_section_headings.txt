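# headings whose medication lists always span before/during/after DCT
medications
current medications
medications on admission
discharge medications
meds
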
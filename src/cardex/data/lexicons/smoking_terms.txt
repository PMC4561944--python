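# terms marking a smoking-history sentence
smoker
smoking
smoke
smokes
smoked
tobacco
cigarette
cigarettes
cigar
packs per day
packs per year
pack years
pack-years
ppd
nonsmoker
non-smoker
ex-smoker
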
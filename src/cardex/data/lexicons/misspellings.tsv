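# observed misspelling -> corrected form
pravastain	pravastatin
obeise	obese
diabetis	diabetes
hypertention	hypertension
atenalol	atenolol
metformen	metformin
lisinipril	lisinopril
cholesteral	cholesterol
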
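# short form -> canonical long form (acyclic, exact match, case-insensitive)
dm	diabetes mellitus
dm2	diabetes type 2
dmii	diabetes type 2
dm type ii	diabetes type 2
dm type 2	diabetes type 2
niddm	diabetes type 2
iddm	diabetes type 1
htn	hypertension
cad	coronary artery disease
chd	coronary heart disease
hl	hyperlipidemia
hld	hyperlipidemia
asa	aspirin
ntg	nitroglycerin
tng	nitroglycerin
hctz	hydrochlorothiazide
mi	myocardial infarction
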
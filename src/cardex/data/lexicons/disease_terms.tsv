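# disease/disorder mention terms -> risk factor
diabetes	DIABETES
diabetes mellitus	DIABETES
diabetes type 2	DIABETES
diabetes type 1	DIABETES
type 2 diabetes	DIABETES
type 1 diabetes	DIABETES
type ii diabetes	DIABETES
type i diabetes	DIABETES
diabetic	DIABETES
hypertension	HYPERTENSION
hypertensive	HYPERTENSION
coronary artery disease	CAD
coronary heart disease	CAD
coronary disease	CAD
ischemic heart disease	CAD
hyperlipidemia	HYPERLIPIDEMIA
hypercholesterolemia	HYPERLIPIDEMIA
dyslipidemia	HYPERLIPIDEMIA
obesity	OBESITY
obese	OBESITY
morbid obesity	OBESITY
morbidly obese	OBESITY
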
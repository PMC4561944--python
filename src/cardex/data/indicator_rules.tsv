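# provenance	selector	risk_factor	indicator
# provenance: disease | lab | medication; selector: mention subtype or lab kind
# risk_factor "*" = taken from the item; indicator "category" = the medication category
disease	mention	*	mention
disease	event	CAD	event
disease	test result	CAD	test result
disease	symptom	CAD	symptom
lab	BP	HYPERTENSION	high blood pressure
lab	A1C	DIABETES	high A1c
lab	GLUCOSE	DIABETES	high glucose
lab	TOTAL_CHOL	HYPERLIPIDEMIA	high cholesterol
lab	LDL	HYPERLIPIDEMIA	high LDL
lab	BMI	OBESITY	BMI
medication	*	MEDICATION	category
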
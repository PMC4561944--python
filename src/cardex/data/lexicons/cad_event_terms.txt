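# CAD "event" indicator phrases
myocardial infarction
heart attack
angioplasty
stent placement
stent
cabg
coronary artery bypass graft
bypass surgery
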
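# canonical section-heading phrases
record date
chief complaint
history of present illness
past medical history
medications
current medications
medications on admission
discharge medications
allergies
family history
social history
review of systems
physical exam
physical examination
vital signs
labs
laboratory data
hospital course
assessment
plan
assessment and plan
impression
problems
problem list
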
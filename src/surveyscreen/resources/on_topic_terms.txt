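# Care-related terms; their presence vetoes the off-topic rule
doctor
physician
oncologist
nurse
provider
cancer
tumor
chemo
chemotherapy
radiation
surgery
treatment
appointment
visit
telehealth
video visit
care
health
clinic
hospital
symptom
medication
prescription
insurance
diagnosis
scan
screening
survivor
pain
therapy
follow-up
followup
port
infusion
bloodwork
lab
results
specialist
family
support
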
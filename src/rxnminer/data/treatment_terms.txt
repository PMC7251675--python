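# Clinical-trial / treatment vocabulary; sentences mentioning these terms
# describe therapy rather than chemistry, so co-occurring chemicals are
# vetoed.
patient
patients
treatment
treated
therapy
therapeutic
trial
clinical
placebo
dose
dosage
administered
administration
prophylaxis
regimen
intervention
randomized
randomised
mg/kg
outpatient
inpatient
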
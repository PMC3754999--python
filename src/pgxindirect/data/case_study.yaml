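# CYP2C19 genotype and choice of anti-platelet therapy after acute
# coronary syndrome: ticagrelor (alpha) vs clopidogrel (beta).
#
# Inputs: unstratified hazard ratio for cardiovascular events 0.84
# (95% CI 0.77-0.92), used as a risk ratio (rare-event approximation);
# association RR for CYP2C19 loss-of-function carriers vs non-carriers on
# clopidogrel 1.18 (95% CI 1.09-1.28) from meta-analysis; no genotype
# effect assumed off clopidogrel (fixed RR = 1); LoF carriage prevalence
# 28.0% in a predominantly Caucasian population.
scenario:
  prevalence:
    point: 0.28
  rr_assoc_alpha:
    fixed: 1.0
  rr_assoc_beta:
    point: 1.18
    ci: [1.09, 1.28]
  rr_overall:
    point: 0.84
    ci: [0.77, 0.92]
  labels:
    arm_alpha: ticagrelor
    arm_beta: clopidogrel
    marker_pos: CYP2C19 LoF carrier
    marker_neg: CYP2C19 LoF non-carrier
analysis: estimate
n_sims: 10000
ci_level: 0.95
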
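# Case-study fixtures: observed strategy means and the parameter overrides
# reported for each supervision program. All other payoff constants fall back
# to the package's reference parameterization when a case is simulated.

[saudi_tb]
description = "Tuberculosis treatment adherence supervision in Saudi Arabia (community mobile outreach teams and a public reporting platform)"
observed_delta = 0.795
observed_eta = 0.825
observed_zeta = 0.733

[saudi_tb.overrides]
mu = 0.8
vm2 = 20
theta = 0.6

[guangdong_covid]
description = "COVID-19 vaccination compliance supervision in Guangdong, China (mobile outreach teams plus a public reporting platform)"
observed_delta = 0.72
observed_eta = 0.91
observed_zeta = 0.85

[guangdong_covid.overrides]
mu = 0.83
vm2 = 18
theta = 0.7

[vietnam_antibiotics]
description = "Antibiotic prescription compliance supervision in rural Vietnamese clinics (stewardship-trained outreach teams and a toll-free public hotline)"
observed_delta = 0.65
observed_eta = 0.76
observed_zeta = 0.70

[vietnam_antibiotics.overrides]
mu = 0.78
vm2 = 22
theta = 0.65
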
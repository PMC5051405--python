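# Niger parameter set (all costs US$2014; percentages as printed).
# Transport cost is a single published figure; the scalar broadcasts to all quintiles.
name: Niger
percent: true
population_15_19: 1021000
mmr: 553
complicated_fraction: 15
rr_by_age: [4.6, 1.0, 1.0, 1.0, 1.0]
pregnant_by_age: [3, 12, 16, 19, 18]
pregnant_by_quintile: [41, 43, 37, 32, 19]
usage_by_quintile: [13, 19, 22, 30, 71]
oop_medical_by_quintile: [97, 127, 140, 124, 152]
oop_transport_by_quintile: 4
gdp_per_capita: 427
gini: 0.32
education_effect: 18
education_effect_se: 2
education_cost_per_pupil: 72
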
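# India variant: identical to the india fixture except for the skilled-birth-attendance
# coverage vector, which here follows the narrative-methods figures (19/29/42/58/80%)
# rather than the parameter table (24/34/48/64/85%). Kept for sensitivity exploration.
name: India (text usage)
percent: true
population_15_19: 58400000
mmr: 174
complicated_fraction: 15
rr_by_age: [4.6, 1.0, 1.0, 1.0, 1.0]
pregnant_by_age: [1, 3, 5, 9, 12]
pregnant_by_quintile: [19, 17, 13, 8, 3]
usage_by_quintile: [19, 29, 42, 58, 80]
oop_medical_by_quintile: [58, 62, 70, 81, 108]
oop_transport_by_quintile: [8, 8, 8, 8, 6]
gdp_per_capita: 1596
gini: 0.34
education_effect: 18
education_effect_se: 2
education_cost_per_pupil: 258
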
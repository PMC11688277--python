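condition,population_affected_pct,service_coverage_pct,mortality_rate_pct,personalization_needs_pct
Cardiovascular,35,65,15,70
Respiratory,20,50,12,60
Diabetes,15,40,8,55
Mobility issues,30,55,10,65
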
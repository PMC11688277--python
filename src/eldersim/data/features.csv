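feature,importance_pct,current_availability_pct,technical_difficulty,expected_coverage_5yr_pct
Real-time monitoring,90,70,4,95
Predictive accuracy,85,60,5,90
User satisfaction,78,65,3,85
Cost-effectiveness,80,55,4,88
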
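# synthetic piecewise-linear exposure-response curve: relative risk of
# all-cause mortality vs weekly leisure-time physical activity.
# Constructed stand-in; not a published hazard-ratio fit.
exposure_met_hr_week,relative_risk
0.0,1.0
3.75,0.89
7.5,0.8
15.0,0.69
22.5,0.64
40.0,0.62
75.0,0.61
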
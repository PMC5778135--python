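disease,age_bin,alpha,gamma,delta
COPD,,0.58,0.0092,0.69
LC,,0.30,0.0120,0.74
IHD,25-29,1.60,0.040,0.47
IHD,30-34,1.45,0.040,0.47
IHD,35-39,1.31,0.040,0.47
IHD,40-44,1.18,0.040,0.47
IHD,45-49,1.06,0.040,0.47
IHD,50-54,0.95,0.040,0.47
IHD,55-59,0.85,0.040,0.47
IHD,60-64,0.76,0.040,0.47
IHD,65-69,0.67,0.040,0.47
IHD,70-74,0.59,0.040,0.47
IHD,75-79,0.51,0.040,0.47
IHD,80+,0.44,0.040,0.47
stroke,25-29,1.30,0.050,0.45
stroke,30-34,1.18,0.050,0.45
stroke,35-39,1.07,0.050,0.45
stroke,40-44,0.97,0.050,0.45
stroke,45-49,0.87,0.050,0.45
stroke,50-54,0.78,0.050,0.45
stroke,55-59,0.70,0.050,0.45
stroke,60-64,0.62,0.050,0.45
stroke,65-69,0.55,0.050,0.45
stroke,70-74,0.48,0.050,0.45
stroke,75-79,0.42,0.050,0.45
stroke,80+,0.36,0.050,0.45
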
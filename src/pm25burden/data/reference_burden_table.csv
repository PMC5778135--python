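decade,ssp,rcp45,rcp85
2011-2020,ssp1,0.77,0.79
2011-2020,ssp2,0.80,0.82
2011-2020,ssp3,0.81,0.83
2011-2020,ssp4,0.80,0.83
2011-2020,ssp5,0.77,0.79
2021-2030,ssp1,0.67,0.69
2021-2030,ssp2,0.73,0.75
2021-2030,ssp3,0.80,0.82
2021-2030,ssp4,0.76,0.78
2021-2030,ssp5,0.65,0.67
2031-2040,ssp1,0.62,0.64
2031-2040,ssp2,0.70,0.72
2031-2040,ssp3,0.83,0.85
2031-2040,ssp4,0.75,0.78
2031-2040,ssp5,0.57,0.59
2041-2050,ssp1,0.56,0.59
2041-2050,ssp2,0.66,0.70
2041-2050,ssp3,0.84,0.89
2041-2050,ssp4,0.73,0.77
2041-2050,ssp5,0.50,0.53
2051-2060,ssp1,0.47,0.52
2051-2060,ssp2,0.59,0.65
2051-2060,ssp3,0.84,0.93
2051-2060,ssp4,0.66,0.73
2051-2060,ssp5,0.41,0.45
2061-2070,ssp1,0.39,0.46
2061-2070,ssp2,0.50,0.58
2061-2070,ssp3,0.80,0.94
2061-2070,ssp4,0.55,0.66
2061-2070,ssp5,0.32,0.37
2071-2080,ssp1,0.30,0.39
2071-2080,ssp2,0.40,0.52
2071-2080,ssp3,0.73,0.94
2071-2080,ssp4,0.44,0.56
2071-2080,ssp5,0.24,0.30
2081-2090,ssp1,0.23,0.31
2081-2090,ssp2,0.33,0.45
2081-2090,ssp3,0.68,0.92
2081-2090,ssp4,0.34,0.46
2081-2090,ssp5,0.17,0.24
2091-2100,ssp1,0.18,0.25
2091-2100,ssp2,0.28,0.37
2091-2100,ssp3,0.66,0.88
2091-2100,ssp4,0.28,0.37
2091-2100,ssp5,0.14,0.18
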
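source,PP_mean,PP_min,PP_max,WC_mean,WC_min,WC_max,HS_mean,HS_min,HS_max
Enteric fermentation (CH4),7.09,6.16,8.02,7.7,6.43,9.70,7.52,5.24,9.61
Manure management (CH4),1.36,0.73,1.78,1.83,1.11,2.56,1.68,1.27,2.59
Manure management (direct N2O),1.15,0.99,1.34,1.06,0.66,1.38,1.06,0.70,1.32
Manure management (indirect volatilisation N2O),0.2,0.17,0.22,0.18,0.11,0.23,0.18,0.12,0.23
Barley production,0.56,0.44,0.69,0.62,0.46,0.90,0.61,0.50,0.87
Ammonium nitrate production,3.56,2.78,4.39,0.53,0.39,0.76,3.32,2.73,4.72
Fertiliser application (N2O),2.03,1.59,2.50,0.3,0.23,0.44,1.89,1.56,2.69
Urine and dung from ewes on pasture (N2O),0.6,0.47,0.74,0.67,0.50,0.97,0.66,0.54,0.94
Farmyard manure application (N2O),0.43,0.25,0.55,0.45,0.30,0.62,0.52,0.40,0.78
Crop residues (N2O),,,,0.33,0.25,0.48,0.33,0.27,0.46
Indirect emissions from leaching (N2O),0.2,0.17,0.24,0.11,0.08,0.14,0.2,0.15,0.29
Urine and dung from cattle on pasture (N2O),0.25,0.19,0.31,0.21,0.13,0.29,0.19,0.11,0.27
Single superphosphate production,0.03,0.02,0.04,0.18,0.14,0.27,0.03,0.03,0.05
Others,1.03,0.80,1.26,1.8,1.34,2.58,1.97,1.61,2.80
Total,18.47,16.32,21.71,15.96,13.73,20.90,20.17,16.63,25.61
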
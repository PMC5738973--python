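parameter,label,unit,PP_mean,PP_sd,WC_mean,WC_sd,HS_mean,HS_sd,p_value
entry_weight,Entry weight,kg,279,32.08,279,28.76,284,35.76,0.80
finishing_weight,Finishing weight,kg,607,50.75,582,47.15,590,39.23,0.12
total_growth,Total growth,kg,328,41.68,304,45.73,307,38.67,0.05
days_on_platform,Time on Farm Platform,d,448,40.33,461,43.68,453,31.97,0.46
adg,Average daily weight gain,kg/d,0.76,0.10,0.68,0.10,0.70,0.08,<0.01
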
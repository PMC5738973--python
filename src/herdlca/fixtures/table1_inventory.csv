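variable,label,unit,PP,WC,HS
area,Area,ha,21.61,20.85,21.45
fertiliser_area,Fertiliser area,ha,21.24,20.52,21.03
fym_area,FYM area,ha,18.90,17.97,18.34
yield_dm,Yield,kg DM/ha,11474,10780,10417
fertiliser_n,Fertiliser applied N,kg,4951,681,4346
fertiliser_p,Fertiliser applied P,kg,206,1125,208
fertiliser_k,Fertiliser applied K,kg,554,454,312
lime,Lime,kg,0,3002,4361
fym,FYM,t,118,118,98
glyphosate,Glyphosate,kg,0,7.51,15.25
fluroxypyr,Fluroxypyr,kg,0,0,0.98
seed_grass,Seeds Grass,kg,0,734,650
seed_clover,Seeds Clover,kg,0,42,0
diesel,Diesel for machinery,l,342,1181,1295
soybean,Soybean,kg,651,651,672
straw,Straw,kg,38920,39894,39685
soybean_sea,Transport Soybean (sea),tkm,6267,6267,6469
soybean_road,Transport Soybean (road),tkm,155,155,160
straw_road,Transport Straw (road),tkm,2436,2497,2484
fertiliser_road,Transport Fertiliser (road),tkm,2444,2252,3949
pasture_de,Pasture quality DE,%,77.55,77.7,76.78
pasture_cp,Pasture quality CP,%,20.72,20.12,17.41
silage_de,Silage quality DE,%,65.76,64.05,64.66
silage_cp,Silage quality CP,%,11.44,9.24,11.92
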
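year,treatment,yield_per_plant,total_yield,wue,tss,vc,oa,ssc,sar
2022,T1,1.28,56.50,38.18,5.27,154.53,0.43,23.19,4.67
2022,T2,1.14,49.06,40.83,5.89,183.60,0.48,29.58,6.15
2022,T3,1.01,43.39,42.22,6.60,172.42,0.50,30.42,6.51
2023,T1,1.30,54.11,26.60,4.64,130.70,0.48,21.02,4.18
2023,T2,1.13,48.21,31.39,5.25,153.88,0.54,25.33,4.80
2023,T3,0.96,40.92,33.22,5.45,154.67,0.55,26.07,4.89
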
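year,stage,n_days,mean_dar,mean_vpd,mean_ta,mean_w
2022,flowering_fruit_setting,43,83.67,0.48,21.27,0.10
2022,picking,61,50.60,0.27,16.06,0.09
2023,flowering_fruit_setting,34,119.70,0.71,21.99,0.12
2023,picking,38,99.21,0.84,26.23,0.17
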
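year,treatment,day,lai
2022,T1,32,0.43
2022,T1,42,0.94
2022,T1,52,2.30
2022,T1,62,3.54
2022,T1,72,3.69
2022,T1,87,3.51
2022,T2,32,0.54
2022,T2,42,0.85
2022,T2,52,1.50
2022,T2,62,2.36
2022,T2,72,2.64
2022,T2,87,2.53
2022,T3,32,0.41
2022,T3,42,0.61
2022,T3,52,1.23
2022,T3,62,2.00
2022,T3,72,2.36
2022,T3,87,2.31
2023,T1,30,0.53
2023,T1,40,1.00
2023,T1,50,2.07
2023,T1,60,3.27
2023,T1,70,3.58
2023,T1,80,3.65
2023,T2,30,0.56
2023,T2,40,0.86
2023,T2,50,1.44
2023,T2,60,2.19
2023,T2,70,2.57
2023,T2,80,2.64
2023,T3,30,0.61
2023,T3,40,0.85
2023,T3,50,1.29
2023,T3,60,1.99
2023,T3,70,2.33
2023,T3,80,2.39
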
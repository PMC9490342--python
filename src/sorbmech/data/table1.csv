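rh_percent,solubility_g_per_100g_keratin,number_density_per_nm3,water_per_residue,vol_percent_water
10.0,1.85,0.758,0.099,0.97
20.0,2.99,1.215,0.159,1.85
30.0,3.64,1.477,0.194,2.06
40.0,4.28,1.733,0.229,2.54
50.0,4.82,1.951,0.258,2.62
60.0,5.59,2.242,0.298,3.28
70.0,6.29,2.511,0.336,3.83
80.0,7.86,3.098,0.420,5.08
90.0,11.87,4.519,0.634,8.33
100.0,17.19,6.237,0.918,12.65
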
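rh_percent,youngs_modulus_gpa,yield_stress_mpa,yield_strain,failure_stress_mpa,failure_strain,poisson_ratio
0.0,4.65,241,0.195,345,0.997,0.405
10.0,4.45,229,0.177,318,1.042,0.412
20.0,4.32,222,0.162,302,1.086,0.419
30.0,4.20,217,0.149,286,1.135,0.425
40.0,4.07,198,0.137,273,1.148,0.428
50.0,3.92,191,0.123,263,1.159,0.432
60.0,3.78,174,0.114,243,1.196,0.436
70.0,3.67,154,0.102,231,1.229,0.439
80.0,3.50,142,0.091,215,1.302,0.445
90.0,2.97,128,0.079,182,1.407,0.468
100.0,2.10,75,0.071,95,1.594,0.498
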
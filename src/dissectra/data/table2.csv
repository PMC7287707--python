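case_id,stage,tl_vol_cm3,fl_vol_cm3,tl_pmc_cm,fli
1,pre,33.29,77.05,0.44,2.31
1,post,68.29,31.40,1.61,0.46
1,fu,93.32,0.68,1.79,0.01
2,pre,63.40,256.40,0.96,4.04
2,post,106.71,177.17,2.25,1.66
2,fu,187.08,2.53,3.08,0.01
3,pre,100.17,148.53,0.60,1.48
3,post,92.60,133.30,0.64,1.44
3,fu,170.38,87.97,2.67,0.52
4,pre,96.33,138.99,0.87,1.44
4,post,194.11,67.27,2.20,0.35
4,fu,177.95,86.43,2.11,0.49
5,pre,71.09,299.80,0.60,4.22
5,post,136.24,248.98,2.06,1.83
5,fu,106.40,286.74,1.80,2.69
6,pre,,,,
6,post,231.74,109.62,2.34,0.47
6,fu,246.75,61.39,2.32,0.25
7,pre,13.34,2.99,2.33,0.22
7,post,26.96,5.59,2.39,0.21
7,fu,28.49,4.66,2.40,0.16
8,pre,83.18,412.04,0.65,4.95
8,post,182.56,344.43,1.80,1.89
8,fu,130.76,244.89,1.84,1.87
9,pre,26.21,218.30,0.16,8.33
9,post,195.93,56.86,2.56,0.29
9,fu,250.10,211.64,2.71,0.85
10,pre,36.61,299.17,0.20,8.17
10,post,138.12,216.88,1.72,1.57
10,fu,166.44,210.70,1.75,1.27
11,pre,131.00,351.68,0.68,2.68
11,post,244.19,267.25,2.17,1.09
11,fu,250.65,259.73,2.13,1.04
12,pre,19.77,218.37,0.15,11.05
12,post,112.84,138.95,1.87,1.23
12,fu,131.08,124.24,1.80,0.95
13,pre,168.00,212.53,0.76,1.27
13,post,188.16,126.07,1.95,0.67
13,fu,235.22,122.60,2.22,0.52
14,pre,131.50,202.73,0.35,1.54
14,post,178.75,134.08,2.19,0.75
14,fu,227.40,201.11,2.45,0.88
15,pre,121.61,120.66,1.08,0.99
15,post,210.45,88.82,2.08,0.42
15,fu,234.90,89.30,2.25,0.38
16,pre,43.40,388.25,0.56,8.95
16,post,115.63,303.25,1.76,2.62
16,fu,124.95,499.48,1.65,4.00
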
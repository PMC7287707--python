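case_id,stage,total_vol_cm3,followup_months
1,pre,110.34,36
1,post,99.69,36
1,fu,94.00,36
2,pre,319.80,36
2,post,283.88,36
2,fu,189.61,36
3,pre,248.70,36
3,post,225.90,36
3,fu,258.35,36
4,pre,235.32,24
4,post,261.38,24
4,fu,264.38,24
5,pre,370.89,30
5,post,385.22,30
5,fu,393.14,30
6,pre,,12
6,post,341.36,12
6,fu,308.14,12
7,pre,16.33,24
7,post,32.55,24
7,fu,33.15,24
8,pre,495.22,12
8,post,526.99,12
8,fu,375.65,12
9,pre,244.51,36
9,post,252.79,36
9,fu,461.74,36
10,pre,335.78,12
10,post,355.00,12
10,fu,377.14,12
11,pre,482.68,6
11,post,511.44,6
11,fu,510.38,6
12,pre,238.14,6
12,post,251.79,6
12,fu,255.32,6
13,pre,380.53,6
13,post,314.23,6
13,fu,357.82,6
14,pre,334.23,6
14,post,312.83,6
14,fu,428.51,6
15,pre,242.27,1
15,post,299.27,1
15,fu,324.20,1
16,pre,431.65,12
16,post,418.88,12
16,fu,624.43,12
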
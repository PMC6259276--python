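# Actual pEC50, model-predicted pEC50 and residuals (actual - predicted) for
# the CoMFA and CoMSIA models of the 26-compound series, as printed in the
# published activity/prediction table. Residuals are the printed values; they
# agree with actual - predicted to the table's rounding (+/-0.0015).
compound_id,pec50_actual,pec50_pred_comfa,residual_comfa,pec50_pred_comsia,residual_comsia,subset
1,9.523,9.548,-0.025,9.53,-0.007,train
2,8.523,8.111,0.412,7.991,0.532,train
3,9.222,9.191,0.031,9.279,-0.057,train
4,9.398,9.454,-0.056,9.317,0.081,train
5,7.721,7.683,0.038,7.82,-0.099,train
6,7.509,7.587,-0.078,7.526,-0.017,train
7,7.509,7.688,-0.179,7.608,-0.099,test
8,7.000,6.982,0.018,7.028,-0.028,train
9,8.222,8.205,0.017,8.124,0.098,train
10,10.301,10.355,-0.054,10.248,0.053,train
11,7.482,7.532,-0.051,7.541,-0.060,train
12,8.456,8.433,0.023,8.438,0.018,train
13,6.801,7.173,-0.372,7.102,-0.301,test
14,8.796,8.762,0.034,8.997,-0.201,train
15,9.824,9.811,0.013,9.953,-0.129,test
16,10.000,9.975,0.025,10.006,-0.006,test
17,8.602,8.774,-0.172,8.619,-0.017,train
18,10.097,9.989,0.108,10.045,0.052,train
19,9.959,9.92,0.039,9.939,0.020,train
20,6.030,6.054,-0.024,5.987,0.043,train
21,8.208,8.164,0.044,8.195,0.013,train
22,8.114,8.096,0.018,8.138,-0.025,train
23,7.398,7.401,-0.003,7.394,0.004,train
24,7.854,7.858,-0.004,7.995,-0.141,train
25,8.678,8.9,-0.222,8.527,0.151,test
26,8.046,8.36,-0.314,8.306,-0.260,train
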
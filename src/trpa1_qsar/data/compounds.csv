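# 26 dibenz[b,e]azepine / dibenz[b,f][1,4]oxazepine TRPA1 agonists.
# position: ring position label of the substituent (empty for unsubstituted
#   parents); bridge: atom at the 11-position (O, CH2 or S).
# The printed structure table lists compound 8 as "8-COOMe2"; this is encoded
#   as COOMe (the only valence-sane reading, and the one the SAR discussion of
#   the series uses).
# The structure table and the SAR discussion disagree on compound 13
#   (8-CN vs 10-Br) and compound 24 (9-OMe vs 8-COOMe); the structure table
#   assignments are used throughout.
compound_id,substituent_position,substituent_group,bridge_atom,pec50_actual,subset
1,,H,O,9.523,train
2,,H,CH2,8.523,train
3,1,COOMe,CH2,9.222,train
4,2,COOMe,CH2,9.398,train
5,3,COOMe,CH2,7.721,train
6,4,COOMe,CH2,7.509,train
7,7,COOMe,CH2,7.509,test
8,8,COOMe,CH2,7.000,train
9,9,COOMe,O,8.222,train
10,10,COOMe,O,10.301,train
11,8,Br,CH2,7.482,train
12,10,Br,CH2,8.456,train
13,8,CN,CH2,6.801,test
14,10,CN,CH2,8.796,train
15,10,CN,O,9.824,test
16,1,CN,O,10.000,test
17,10,CONH2,CH2,8.602,train
18,10,CONH2,O,10.097,train
19,1,CONH2,O,9.959,train
20,8,COOiPr,CH2,6.030,train
21,10,COOnBu,CH2,8.208,train
22,10,CONH(CH2)3OMe,CH2,8.114,train
23,10,CONEt2,CH2,7.398,train
24,9,OMe,O,7.854,train
25,9,OH,O,8.678,test
26,,H,S,8.046,train
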
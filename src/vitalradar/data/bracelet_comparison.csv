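trial,heart_radar,heart_bracelet,heart_err_pct,resp_radar,resp_bracelet,resp_err_pct
1,69,71,2.8,14,14,0.0
2,69,72,4.2,16,15,6.7
3,72,75,4.0,16,17,5.9
4,76,74,2.7,19,21,9.5
5,85,80,6.3,19,20,5.0
6,66,70,5.7,21,23,8.7
7,71,74,4.1,22,22,0.0
8,80,80,0.0,24,24,0.0
9,97,101,4.0,17,18,5.6
10,111,106,4.7,21,20,5.0
11,70,71,1.4,22,23,4.3
12,81,85,4.7,24,23,4.3
13,92,89,3.4,18,19,5.3
14,105,101,4.0,27,26,3.8
15,109,112,2.7,30,29,3.4
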
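frame,V_middle,V_edge,ratio_s,N_middle,N_edge,ratio_n
1,22.70,22.07,1.03,10,6,1.67
10,15.89,12.51,1.27,11,5,2.20
19,12.61,11.59,1.09,11,5,2.20
28,13.02,10.47,1.24,11,5,2.20
37,8.28,7.42,1.12,12,4,3.00
46,9.13,4.77,1.91,11,5,2.20
55,6.43,0.39,16.63,8,8,1.00
64,8.65,0.39,22.27,6,10,0.60
73,10.16,0.16,63.93,3,13,0.23
82,3.86,0.16,24.30,3,13,0.23
91,2.86,0.08,35.47,3,13,0.23
100,1.88,0.07,25.12,2,14,0.14
109,1.88,0.12,15.60,2,14,0.14
118,5.10,0.12,42.34,2,14,0.14
127,1.93,0.47,4.14,1,15,0.07
136,7.00,0.00,0.00,1,15,0.07
145,1.14,0.00,0.00,1,15,0.07
154,0.00,0.07,0.00,0,16,0.00
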
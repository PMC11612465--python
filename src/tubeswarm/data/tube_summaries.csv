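tube_id,ratio_s,ratio_n,angle_deg,cosine
A,1.42,2.47,29.05,0.87
B,1.71,4.33,5.52,1.00
C,1.40,2.48,34.12,0.83
D,1.52,3.00,22.03,0.93
E,1.51,4.76,23.84,0.91
F,1.14,1.67,51.00,0.63
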
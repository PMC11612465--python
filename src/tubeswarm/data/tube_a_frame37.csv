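number,x,y,speed_x,speed_y,speed,frame
1,1070.00,618.00,7.00,-8.00,10.63,37
2,1905.00,1078.00,0.00,0.00,0.00,37
3,1132.50,477.00,6.50,-1.00,6.58,37
4,1073.00,612.00,3.00,-5.50,6.26,37
5,1247.00,517.00,11.50,2.50,11.77,37
6,1242.00,502.00,9.50,0.50,9.51,37
7,1905.00,1078.00,0.00,0.00,0.00,37
8,905.40,553.20,8.40,-0.80,8.44,37
9,1264.00,553.00,641.00,525.00,0.00,37
10,985.75,539.50,5.25,-2.50,5.81,37
11,1144.00,569.00,6.50,0.00,6.50,37
12,1263.00,469.00,5.00,1.50,5.22,37
13,1223.50,579.50,11.50,3.50,12.02,37
14,869.80,688.40,6.60,-2.20,6.96,37
15,989.00,540.00,5.00,0.00,5.00,37
16,1139.00,605.00,29.50,-2.00,29.57,37
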
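repair_rate_h,dose_gy,n_fields,tau_min,rbe_printed,verified
0.46,2,2,1,0.998,true
0.46,2,2,3,0.997,true
0.46,2,2,5,0.993,true
0.46,2,2,10,0.990,true
0.46,2,2,30,0.987,false
0.46,2,2,60,0.973,false
0.46,2,4,1,0.998,true
0.46,2,4,3,0.996,false
0.46,2,4,5,0.991,false
0.46,2,4,10,0.987,false
0.46,2,4,30,0.950,false
0.46,2,4,60,0.918,false
0.46,8,2,1,0.997,true
0.46,8,2,3,0.992,false
0.46,8,2,5,0.985,false
0.46,8,2,10,0.981,false
0.46,8,2,30,0.975,false
0.46,8,2,60,0.921,true
0.46,8,4,1,0.997,true
0.46,8,4,3,0.992,false
0.46,8,4,5,0.983,false
0.46,8,4,10,0.975,false
0.46,8,4,30,0.900,true
0.46,8,4,60,0.836,false
1.0,2,2,1,0.999,true
1.0,2,2,3,0.997,false
1.0,2,2,5,0.995,false
1.0,2,2,10,0.990,false
1.0,2,2,30,0.973,false
1.0,2,2,60,0.951,false
1.0,2,4,1,0.997,false
1.0,2,4,3,0.991,false
1.0,2,4,5,0.986,false
1.0,2,4,10,0.973,false
1.0,2,4,30,0.934,false
1.0,2,4,60,0.899,false
1.0,8,2,1,0.998,true
1.0,8,2,3,0.994,false
1.0,8,2,5,0.990,false
1.0,8,2,10,0.981,false
1.0,8,2,30,0.948,false
1.0,8,2,60,0.905,false
1.0,8,4,1,0.994,false
1.0,8,4,3,0.983,false
1.0,8,4,5,0.972,false
1.0,8,4,10,0.948,false
1.0,8,4,30,0.870,false
1.0,8,4,60,0.796,false
2.0,2,2,1,0.998,false
2.0,2,2,3,0.994,false
2.0,2,2,5,0.990,false
2.0,2,2,10,0.981,false
2.0,2,2,30,0.951,false
2.0,2,2,60,0.920,false
2.0,2,4,1,0.994,false
2.0,2,4,3,0.983,false
2.0,2,4,5,0.973,false
2.0,2,4,10,0.951,false
2.0,2,4,30,0.899,false
2.0,2,4,60,0.865,false
2.0,8,2,1,0.996,false
2.0,8,2,3,0.989,false
2.0,8,2,5,0.981,false
2.0,8,2,10,0.964,false
2.0,8,2,30,0.905,false
2.0,8,2,60,0.841,false
2.0,8,4,1,0.989,false
2.0,8,4,3,0.967,false
2.0,8,4,5,0.948,false
2.0,8,4,10,0.905,false
2.0,8,4,30,0.796,false
2.0,8,4,60,0.722,false
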
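symbol,entrez_id,sources,band,sd_ref,sd_array,sd_overall,rank,in_panel
Dolpp1,57170,c,medium,0.16,0.05,0.118,1,True
Mpv17l,93734,c,medium,0.18,0.03,0.129,2,True
Elac2,68626,c,medium,0.19,0.05,0.139,3,True
Pcsk7,18554,c,medium,0.2,0.03,0.143,4,True
Kdm3b,277250,c,medium,0.19,0.07,0.143,5,True
Maea,59003,c,medium,0.21,0.05,0.152,6,True
Fkbp1a,14225,c,high,0.24,0.06,0.174,7,True
Wars2,70560,c,medium,0.24,0.08,0.179,8,True
Auh,11992,c,low,0.24,0.08,0.18,9,True
Efhd2,27984,c,high,0.27,0.02,0.192,10,True
Zc3h11a,70579,c,high,0.28,0.02,0.198,11,True
Rexo5,434234,c,low,0.28,0.03,0.199,12,True
Nupl2,231042,c,low,0.27,0.1,0.204,13,True
Tmed2,56334,c,high,0.31,0.02,0.22,14,True
Grn,14824,c,high,0.33,0.02,0.234,15,True
Eif3a,13669,b,low,0.32,0.09,0.235,16,True
Tbp,21374,d,medium,0.33,0.04,0.235,17,True
Csnk1a1,93687,c,high,0.33,0.08,0.241,18,True
Eif4g2,13690,c,high,0.34,0.03,0.241,19,True
Tnks2,74493,c,high,0.34,0.04,0.242,20,True
F2r,14062,c,high,0.32,0.13,0.243,21,False
Rab23,19335,c,medium,0.34,0.1,0.251,22,False
Myadm,50918,c,high,0.33,0.15,0.256,23,False
Rrp1b,72462,c,medium,0.37,0.07,0.266,24,False
Hprt,15452,d,high,0.37,0.07,0.267,25,False
Canx,12330,c,high,0.35,0.15,0.268,26,False
Eif4h,22384,c,high,0.39,0.04,0.277,27,False
Slc35a5,74102,c,high,0.41,0.03,0.291,28,False
Atp6v0c,11984,c,high,0.45,0.06,0.321,29,False
Ywhaz,22631,d,high,0.45,0.06,0.321,30,False
Mx2,17858,d,low,0.43,0.17,0.328,31,False
Hdgfrp2,15193,c,medium,0.52,0.0,0.368,32,False
Puf60,67959,b,high,0.54,0.01,0.382,33,True
Tfrc,22042,d,high,0.51,0.21,0.39,34,True
Tomm20,67952,c,high,0.56,0.04,0.397,35,False
Psmd4,19185,b,high,0.62,0.0,0.438,36,True
Sdha,66945,d,high,0.69,0.06,0.49,37,False
G6pdx,14381,d,high,0.71,0.04,0.503,38,False
Rhot1,59040,c,high,0.53,0.48,0.504,39,False
Ing3,71777,c,medium,0.78,0.05,0.553,40,False
Gusb,110006,"a,b,d",medium,0.79,0.01,0.559,41,False
Pla2g2a,18780,d,low,0.8,0.03,0.566,42,False
Actb,11461,"a,b,d",high,0.83,0.04,0.588,43,False
Rpl4,67891,b,high,0.85,0.02,0.601,44,True
Gapdh,14433,"a,b,d",high,0.88,0.05,0.623,45,False
Hsp90ab1,15516,d,high,0.92,0.47,0.73,46,False
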
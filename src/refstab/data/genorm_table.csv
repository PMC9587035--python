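gene,preselection_value,preselection_rank,physiologic_value,physiologic_rank,pnd2_5_value,pnd2_5_rank,pnd5_5_value,pnd5_5_rank,pnd14_5_28_5_value,pnd14_5_28_5_rank,male_value,male_rank,female_value,female_rank,low_rin_value,low_rin_rank,hyperoxia_value,hyperoxia_rank
Auh,0.151,8,0.541,10,0.204,8,0.463,13,0.48,16,0.392,8,0.397,7,1.537,22,0.299,1
Csnk1a1,0.199,19,0.375,3,0.317,17,0.382,9,0.42,11,0.231,1,0.224,1,0.908,11,0.407,5
Dolpp1,0.113,1,0.498,7,0.125,4,0.132,1,0.558,21,0.416,10,0.418,8,0.64,5,0.372,4
Efhd2,0.157,9,0.589,13,0.265,13,0.295,5,0.532,20,0.433,12,0.465,11,0.585,4,0.601,13
Eif3a,0.197,16,0.431,5,0.355,20,0.429,12,0.49,17,0.333,5,0.51,15,0.541,3,0.535,10
Eif4g2,0.198,17,0.836,20,0.236,11,0.619,17,0.347,8,0.231,1,0.312,4,0.469,1,0.583,12
Elac2,0.119,4,0.468,6,0.061,1,0.284,4,0.303,7,0.425,11,0.438,9,1.099,15,0.496,8
Grn,0.191,14,0.937,22,0.097,3,0.814,21,0.376,9,0.446,14,0.478,12,1.259,18,0.89,22
Kdm3b,0.121,5,0.555,11,0.165,6,0.253,3,0.5,18,0.476,17,0.52,16,0.469,1,0.745,18
Maea,0.137,6,0.401,4,0.292,15,0.412,11,0.239,5,0.369,7,0.49,13,0.669,6,0.436,6
Mpv17l,0.113,2,1.053,23,0.509,23,0.966,23,0.737,23,0.719,23,0.782,23,1.619,23,0.95,23
Nupl2,0.178,12,0.28,1,0.141,5,0.314,6,0.221,4,0.451,15,0.453,10,0.766,8,0.51,9
Pcsk7,0.118,3,0.513,8,0.061,1,0.132,1,0.514,19,0.406,9,0.542,18,0.868,10,0.474,7
Psmd4,0.358,22,0.568,12,0.278,14,0.334,7,0.189,3,0.44,13,0.575,20,0.704,7,0.562,11
Puf60,0.312,20,0.884,21,0.414,22,0.881,22,0.586,22,0.615,22,0.667,22,1.453,21,0.843,21
Rexo5,0.166,11,0.714,16,0.343,19,0.505,14,0.401,10,0.514,19,0.597,21,0.971,12,0.773,19
Rpl4,0.491,23,0.28,1,0.222,10,0.36,8,0.152,1,0.535,20,0.531,17,1.32,19,0.34,3
Tbp,0.194,15,0.637,14,0.215,9,0.551,15,0.469,15,0.265,3,0.269,3,1.138,16,0.669,15
Tfrc,0.333,21,0.778,18,0.304,16,0.771,20,0.261,6,0.354,6,0.337,5,1.016,13,0.722,17
Tmed2,0.185,13,0.806,19,0.248,12,0.723,19,0.152,1,0.566,21,0.224,1,1.196,17,0.797,20
Tnks2,0.198,18,0.748,17,0.372,21,0.665,18,0.444,13,0.462,16,0.555,19,1.059,14,0.7,16
Wars2,0.15,7,0.676,15,0.189,7,0.585,16,0.459,14,0.492,18,0.5,14,1.384,20,0.631,14
Zc3h11a,0.166,10,0.528,9,0.331,18,0.4,10,0.432,12,0.313,4,0.368,6,0.827,9,0.299,1
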
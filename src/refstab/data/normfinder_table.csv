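gene,preselection_value,preselection_rank,physiologic_value,physiologic_rank,pnd2_5_value,pnd2_5_rank,pnd5_5_value,pnd5_5_rank,pnd14_5_28_5_value,pnd14_5_28_5_rank,male_value,male_rank,female_value,female_rank,low_rin_value,low_rin_rank,hyperoxia_value,hyperoxia_rank
Auh,0.151,8,0.553,10,0.201,7,0.755,16,0.541,17,0.383,9,0.229,1,2.262,22,0.301,3
Csnk1a1,0.199,19,0.278,2,0.217,9,0.275,3,0.314,8,0.286,5,0.393,9,0.817,6,0.333,6
Dolpp1,0.113,1,0.496,8,0.403,18,0.366,4,0.808,22,0.342,7,0.402,10,0.611,4,0.322,5
Efhd2,0.157,9,0.81,15,0.506,20,0.717,15,0.665,19,0.508,14,0.439,12,0.97,8,0.815,17
Eif3a,0.197,16,0.409,6,0.271,12,0.505,9,0.418,12,0.397,10,0.273,4,0.752,5,0.476,8
Eif4g2,0.198,17,0.993,19,0.053,1,1.051,18,0.208,3,0.241,2,0.328,6,1.176,16,0.718,13
Elac2,0.119,4,0.527,9,0.376,16,0.596,14,0.125,2,0.455,13,0.486,15,1.157,14,0.523,9
Grn,0.191,14,1.452,22,0.336,13,1.363,21,0.27,6,0.593,19,0.57,19,1.824,20,1.39,22
Kdm3b,0.121,5,0.608,11,0.257,10,0.519,10,0.578,18,0.557,17,0.526,18,0.986,10,0.872,18
Maea,0.137,6,0.205,1,0.366,15,0.106,2,0.086,1,0.508,15,0.343,8,0.468,3,0.314,4
Mpv17l,0.113,2,2.444,23,1.815,23,1.902,23,2.871,23,2.266,23,2.058,23,2.32,23,1.517,23
Nupl2,0.178,12,0.311,3,0.216,8,0.395,6,0.254,4,0.441,12,0.415,11,0.845,7,0.465,7
Pcsk7,0.118,3,0.476,7,0.39,17,0.492,8,0.704,20,0.582,18,0.33,7,0.372,2,0.529,10
Psmd4,0.358,22,0.616,12,0.509,21,0.475,7,0.258,5,0.741,21,0.516,17,0.99,11,0.743,16
Puf60,0.312,20,1.341,21,0.811,22,1.537,22,0.73,21,1.372,22,1.015,22,1.92,21,1.224,21
Rexo5,0.166,11,0.868,17,0.259,11,0.381,5,0.336,9,0.714,20,0.582,20,1.003,12,0.884,19
Rpl4,0.491,23,0.329,4,0.104,5,0.522,11,0.278,7,0.364,8,0.514,16,1.449,18,0.235,1
Tbp,0.194,15,0.729,13,0.09,4,0.567,13,0.515,16,0.264,4,0.251,3,1.159,15,0.726,14
Tfrc,0.333,21,0.897,18,0.168,6,1.104,20,0.387,11,0.253,3,0.286,5,0.979,9,0.735,15
Tmed2,0.185,13,1.003,20,0.053,2,1.084,19,0.426,13,0.239,1,0.73,21,1.298,17,0.913,20
Tnks2,0.198,18,0.85,16,0.412,19,0.762,17,0.474,15,0.536,16,0.446,13,1.144,13,0.698,12
Wars2,0.15,7,0.774,14,0.089,3,0.545,12,0.462,14,0.406,11,0.456,14,1.675,19,0.547,11
Zc3h11a,0.166,10,0.368,5,0.355,14,0.106,1,0.365,10,0.302,6,0.251,2,0.297,1,0.253,2
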
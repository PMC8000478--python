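tag,category,mean_R,sd_R,mean_G,sd_G,mean_B,sd_B,absmean_R,abssd_R,absmean_G,abssd_G,absmean_B,abssd_B,abs_total
S1,Silver,215,0.6915,215,1.1861,215,1.0148,0.0729,0.0014,0.0720,0.0024,0.0729,0.0021,0.0726
S2,Silver,216,1.1059,216,0.8137,216,0.9248,0.0706,0.0023,0.0696,0.0017,0.0708,0.0019,0.0703
S3,Silver,217,1.7991,216,1.7340,216,1.6046,0.0685,0.0036,0.0696,0.0035,0.0711,0.0033,0.0697
S4,Silver,225,3.0820,227,3.5519,227,2.8720,0.0529,0.0061,0.0487,0.0070,0.0496,0.0056,0.0504
S5,Silver,216,1.1427,216,1.1427,216,1.1427,0.0705,0.0023,0.0705,0.0023,0.0705,0.0023,0.0705
S6,Silver,215,1.0417,215,2.4542,215,1.3113,0.0727,0.0021,0.0717,0.0050,0.0723,0.0027,0.0722
S7,Silver,223,1.4794,224,2.2733,225,2.8816,0.0556,0.0029,0.0545,0.0045,0.0530,0.0056,0.0544
S8,Silver,223,3.1220,224,1.8144,224,1.8144,0.0559,0.0062,0.0543,0.0035,0.0543,0.0035,0.0549
A1,Aged,196,1.3730,199,1.2972,199,1.3730,0.1118,0.0031,0.1055,0.0029,0.1053,0.0030,0.1076
A2,Aged,211,1.7682,213,1.4794,208,0.8193,0.0812,0.0037,0.0755,0.0031,0.0870,0.0017,0.0813
A3,Aged,209,0.6215,212,0.7849,209,3.6928,0.0855,0.0013,0.0784,0.0016,0.0850,0.0076,0.0830
A4,Aged,219,1.2243,222,1.0417,211,1.7207,0.0635,0.0025,0.0576,0.0021,0.0811,0.0036,0.0674
A5,Aged,204,0.7303,207,0.4498,206,0.6433,0.0955,0.0016,0.0887,0.0010,0.0910,0.0014,0.0917
A6,Aged,207,0.6915,210,0.6288,206,0.7849,0.0887,0.0015,0.0817,0.0013,0.0908,0.0017,0.0871
A7,Aged,229,0.6288,234,0.5252,231,0.6065,0.0459,0.0012,0.0356,0.0010,0.0406,0.0012,0.0407
A8,Aged,212,1.0807,217,0.9965,204,0.8023,0.0784,0.0023,0.0680,0.0020,0.0945,0.0017,0.0803
A9,Aged,200,1.8889,204,1.2794,197,2.4011,0.1048,0.0042,0.0955,0.0028,0.1113,0.0054,0.1039
A10,Aged,223,0.8996,224,0.8996,211,3.1397,0.0574,0.0018,0.0537,0.0018,0.0811,0.0067,0.0641
A11,Aged,214,1.3493,220,0.8137,218,1.3322,0.0748,0.0028,0.0616,0.0016,0.0654,0.0027,0.0673
A12,Aged,217,0.6288,222,1.2576,213,0.8841,0.0681,0.0013,0.0590,0.0025,0.0771,0.0018,0.0681
EA1,Extra-aged,207,0.7611,207,1.2015,180,0.4983,0.0884,0.0016,0.0887,0.0026,0.1486,0.0012,0.1086
EA2,Extra-aged,206,0.7240,210,0.8193,191,0.8683,0.0918,0.0016,0.0836,0.0017,0.1236,0.0020,0.0997
EA3,Extra-aged,221,0.9248,224,0.7303,208,0.8469,0.0600,0.0019,0.0537,0.0014,0.0872,0.0018,0.0670
EA4,Extra-aged,215,1.0283,220,0.5509,209,0.8137,0.0731,0.0021,0.0628,0.0011,0.0855,0.0017,0.0738
EA5,Extra-aged,211,1.2576,206,1.1059,169,0.9685,0.0807,0.0026,0.0912,0.0024,0.1780,0.0025,0.1166
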
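department,ED20,ED19,ED18,ED17,ED16,ED15,ED14,ED13,ED12,ED11,ED10,ED9,ED8,ED7,ED6,ED5,ED4,ED3,ED2,ED1,R,R-C
ED20,0.0133,0.0247,0.0144,0.0138,0.01,0.02,0.03,0.03,0.02,0.03,0.03,0.02,0.0278,0.03,0.04,0.04,0.04,0.03,0.03,0.0306,0.5965,-0.647
ED19,0.0100,0.0212,0.0109,0.0103,0.02,0.01,0.03,0.02,0.01,0.03,0.03,0.01,0.0157,0.02,0.02,0.02,0.02,0.01,0.02,0.0279,0.4613,-0.930
ED18,0.0094,0.0106,0.0139,0.0098,0.01,0.03,0.03,0.02,0.02,0.02,0.02,0.03,0.0217,0.02,0.02,0.02,0.02,0.02,0.02,0.0240,0.4537,-0.910
ED17,0.0077,0.0085,0.0085,0.0114,0.00,0.02,0.02,0.02,0.02,0.02,0.02,0.01,0.0190,0.02,0.02,0.02,0.02,0.02,0.02,0.0207,0.3622,-0.934
ED16,0.0440,0.0476,0.0471,0.0454,0.06,0.08,0.08,0.08,0.08,0.09,0.09,0.07,0.0775,0.09,0.09,0.09,0.10,0.08,0.08,0.0850,1.6005,0.1158
ED15,0.0637,0.0791,0.0817,0.0690,0.08,0.13,0.12,0.12,0.11,0.13,0.13,0.10,0.1017,0.12,0.13,0.13,0.13,0.11,0.11,0.1119,2.2539,0.0156
ED14,0.0505,0.0649,0.0643,0.0521,0.06,0.09,0.11,0.10,0.10,0.12,0.12,0.08,0.0841,0.10,0.11,0.11,0.11,0.09,0.09,0.0994,1.8993,-0.569
ED13,0.0509,0.0655,0.0649,0.0627,0.06,0.10,0.11,0.12,0.10,0.13,0.13,0.08,0.0849,0.11,0.11,0.11,0.11,0.09,0.09,0.0936,1.9511,-0.469
ED12,0.0114,0.0126,0.0125,0.0119,0.01,0.02,0.03,0.03,0.03,0.03,0.03,0.02,0.0282,0.03,0.03,0.03,0.03,0.03,0.03,0.0308,0.5358,-1.669
ED11,0.1050,0.1126,0.1114,0.1078,0.11,0.16,0.18,0.18,0.17,0.19,0.19,0.15,0.1539,0.17,0.17,0.17,0.17,0.16,0.16,0.1685,3.1807,0.6089
ED10,0.1050,0.1126,0.1114,0.1078,0.11,0.16,0.18,0.18,0.17,0.19,0.19,0.15,0.1539,0.17,0.17,0.17,0.17,0.16,0.16,0.1685,3.1807,0.6089
ED9,0.0517,0.0562,0.0557,0.0534,0.06,0.10,0.11,0.11,0.09,0.12,0.12,0.09,0.0828,0.11,0.11,0.11,0.11,0.11,0.11,0.1118,1.9383,-0.116
ED8,0.0517,0.0562,0.0557,0.0534,0.06,0.10,0.11,0.11,0.08,0.12,0.12,0.08,0.0895,0.11,0.11,0.11,0.11,0.11,0.11,0.1118,1.9383,-0.058
ED7,0.0439,0.0476,0.0471,0.0453,0.04,0.08,0.09,0.09,0.06,0.09,0.09,0.07,0.0635,0.09,0.09,0.09,0.09,0.09,0.09,0.0909,1.5729,-0.824
ED6,0.1204,0.1294,0.1280,0.1237,0.13,0.20,0.22,0.22,0.20,0.23,0.21,0.19,0.1917,0.22,0.22,0.22,0.22,0.21,0.21,0.2132,3.8839,1.4116
ED5,0.1206,0.1297,0.1283,0.1240,0.13,0.20,0.22,0.22,0.20,0.23,0.23,0.19,0.1921,0.22,0.22,0.22,0.22,0.21,0.21,0.2136,3.8916,1.4193
ED4,0.1206,0.1297,0.1283,0.1240,0.13,0.20,0.22,0.22,0.20,0.23,0.23,0.19,0.1921,0.22,0.22,0.22,0.22,0.21,0.21,0.2136,3.8917,1.4092
ED3,0.0875,0.0939,0.0929,0.0898,0.09,0.14,0.15,0.15,0.14,0.16,0.16,0.14,0.1385,0.15,0.15,0.15,0.16,0.15,0.15,0.1515,2.7805,0.5329
ED2,0.0875,0.0940,0.0930,0.0899,0.09,0.14,0.15,0.15,0.14,0.16,0.16,0.14,0.1386,0.15,0.16,0.16,0.16,0.15,0.15,0.1550,2.7858,0.5041
ED1,0.0875,0.0940,0.0930,0.0899,0.09,0.14,0.15,0.15,0.14,0.16,0.16,0.14,0.1386,0.15,0.16,0.16,0.16,0.15,0.15,0.1583,2.7858,0.5041
C,1.2435,1.3916,1.3638,1.2963,1.48,2.23,2.46,2.42,2.20,2.57,2.57,2.05,1.9971,2.39,2.47,2.47,2.48,2.24,2.28,2.2816,,
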
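criterion,weight,ED20,ED19,ED18,ED17,ED16,ED15,ED14,ED13,ED12,ED11,ED10,ED9,ED8,ED7,ED6,ED5,ED4,ED3,ED2,ED1
MR1,0.07211,0.86,0.288,2.163,1.874,2.307,2.019,2.163,0,0.288,0.288,0.288,0,0,0.865,0,0,0,0,0,0
MR2,0.11057,0,0,0,0,0,0,1.769,2.211,0.884,7.961,7.961,0,0,1.326,0,0,0,0,0,0
MR3,0.10817,3.02,0.216,0,0,1.307,0,3.894,4.110,4.110,0.432,0.432,0,0,0.432,0,0,0,0,0,0
MR4,0.10336,4.13,4.548,5.374,7.235,5.788,2.894,7.028,1.033,1.860,6.408,6.408,0.413,0.413,4.961,1.653,1.653,1.653,0.826,0.826,0.826
MR5,0.05528,2.98,2.764,5.086,5.307,3.759,2.543,1.105,2.874,2.985,2.874,2.874,2.874,2.874,3.538,4.644,4.644,4.644,2.764,2.874,2.874
MR6,0.06971,3.34,1.812,3.903,3.346,3.625,1.673,2.927,4.043,3.206,2.927,2.788,2.509,4.461,4.043,2.230,2.230,2.230,2.788,2.788,2.788
MR7,0.06971,3.62,1.115,3.625,3.625,1.673,3.067,1.394,1.673,1.394,3.067,3.067,1.951,2.509,0.557,0.557,0.557,0.557,3.067,1.115,1.115
MR8,0.04086,1.71,0.735,2.043,1.552,2.206,1.144,1.552,1.961,1.389,3.269,3.269,1.634,1.798,2.124,1.798,1.798,1.798,1.634,1.798,1.798
MR9,0.06490,3.24,2.076,4.413,3.634,3.375,3.894,2.596,2.076,1.817,2.206,2.206,2.855,3.115,1.298,2.336,2.336,2.336,3.245,2.855,2.855
MR10,0.40865,3.26,1.798,2.778,2.778,2.533,2.615,2.124,2.288,2.043,2.370,3.514,2.615,1.879,1.225,2.288,2.124,2.124,1.471,1.389,1.389
MR11,0.09855,2.16,0.591,3.350,3.350,3.350,1.576,1.971,1.576,1.182,2.365,2.365,1.576,1.576,6.701,0.788,0.788,0.788,1.971,1.182,1.182
MR12,0.04567,1.55,1.552,1.826,2.192,2.100,1.826,2.100,1.918,1.918,1.278,2.374,2.192,2.192,1.278,1.826,2.009,1.735,1.461,1.461,1.461
Infection Risk,0.12019,6.61,8.173,7.692,8.173,3.605,1.201,5.408,4.807,12.01,6.009,6.009,3.605,2.403,7.692,10.09,10.81,10.21,5.408,4.807,4.807
Ws,,36.5,25.67,42.25,43.07,36.05,24.45,36.03,30.57,35.10,41.46,43.56,22.23,23.22,36.04,28.22,28.96,28.08,24.63,21.10,21.10
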
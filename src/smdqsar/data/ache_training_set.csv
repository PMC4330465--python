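id,name,smiles,ic50_uM,ic50_lo_uM,ic50_hi_uM,pic50,protonation
1,AL011,,13.0,11.3,15.0,4.89,
2,AL013,,445,321,616,3.35,
3,AL012,,,,,2.00,
4,AL007,,69.5,54.6,88.5,4.16,
5,AL008,,101,82.7,123,4.00,
6,AL006,,12.8,11.0,15.0,4.89,
7,AL015,,4250,1730,10500,2.37,
8,AL016,,12.0,10.2,14.0,4.92,
9,AL005,,67.7,57.4,79.8,4.17,
10,AL014,,323,207,504,3.49,
11,AL009,,2430,1240,4790,2.61,
12,AL010,,78.0,65.3,93.1,4.11,
13,AL017,,25.0,21.2,29.6,4.60,
14,AL021,,6.6,5.6,8.0,5.18,
15,AL022,,22.2,19.7,24.9,4.65,
16,AL018,,109,87.2,137,3.96,
17,AL020,,4204,165,107000,2.38,
18,AL019,,136,118,156,3.87,
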
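a1_id,b1_id,auc,threshold,sampen_a1,sampen_b1,accuracy_pct
7,4,0.89,0.2611,0.2998,0.2597,100
4,9,0.90,0.2611,0.3652,0.2585,100
3,1,0.93,0.2611,0.2280,0.2577,0
1,7,0.89,0.2611,0.3098,0.2278,100
4,6,0.89,0.2611,0.3652,0.2222,100
11,4,0.97,0.2605,0.1798,0.2597,0
14,9,0.90,0.2611,0.3985,0.2585,100
14,2,0.88,0.2611,0.3985,0.1529,100
11,7,0.96,0.2611,0.1798,0.2278,0
14,6,0.89,0.2611,0.3985,0.2222,100
8,8,0.89,0.2611,0.4708,0.2072,100
13,1,0.90,0.2611,0.3738,0.2577,100
8,7,0.89,0.2611,0.4708,0.2278,100
1,1,0.90,0.2611,0.3098,0.2577,100
6,9,0.90,0.2611,0.3099,0.2585,100
6,1,0.90,0.2611,0.3099,0.2577,100
2,6,0.89,0.2645,0.2625,0.2222,0
1,7,0.89,0.2611,0.3098,0.2278,100
3,2,0.92,0.2611,0.2280,0.1529,0
4,1,0.90,0.2611,0.3652,0.2577,100
6,5,0.89,0.2611,0.3099,0.2174,100
8,7,0.89,0.2611,0.4708,0.2278,100
7,2,0.88,0.2611,0.2998,0.1529,100
14,2,0.88,0.2611,0.3985,0.1529,100
6,4,0.90,0.2605,0.3099,0.2597,100
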
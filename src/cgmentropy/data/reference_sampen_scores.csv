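record_id,label,sampen
1,A1,0.3098
2,A1,0.2625
3,A1,0.2280
4,A1,0.3652
5,A1,0.2713
6,A1,0.3099
7,A1,0.2998
8,A1,0.4708
9,A1,0.2694
10,A1,0.5985
11,A1,0.1798
12,A1,0.2859
13,A1,0.3738
14,A1,0.3985
1,B1,0.2577
2,B1,0.1529
3,B1,0.2367
4,B1,0.2597
5,B1,0.2174
6,B1,0.2222
7,B1,0.2278
8,B1,0.2072
9,B1,0.2585
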
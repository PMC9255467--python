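comparison	scope	count_a	count_b
down_vs_up	all_tissues	4592	1692
down_vs_up	circulatory	255	94
down_vs_up	adipose	1426	1212
down_vs_up	digestive	2664	135
down_vs_up	skeletal_muscle	247	251
specific_vs_shared	circulatory	242	89
specific_vs_shared	adipose	1989	342
specific_vs_shared	digestive	1875	409
specific_vs_shared	skeletal_muscle	244	217
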
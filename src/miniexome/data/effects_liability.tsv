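gene	snp	maf	beta
AKT3	C1S11396	0.000717	0.340456
BCL2L11	C2S2286	0.000717	0.274592
BCL2L11	C2S2288	0.002869	0.563598
BCL2L11	C2S2307	0.000717	0.606816
ELAVL4	C1S3181	0.000717	0.64359
ELAVL4	C1S3182	0.000717	0.214219
HSP90AA1	C14S3630	0.000717	0.0579258
HSP90AA1	C14S3695	0.000717	0.152617
HSP90AA1	C14S3704	0.003587	0.0789197
HSP90AA1	C14S3706	0.258250	0.0874168
NRAS	C1S5748	0.000717	0.409806
PIK3C2B	C1S9164	0.001435	0.205094
PIK3C2B	C1S9165	0.000717	0.141183
PIK3C2B	C1S9172	0.004304	0.508901
PIK3C2B	C1S9173	0.001435	0.12026
PIK3C2B	C1S9174	0.000717	0.634406
PIK3C2B	C1S9189	0.006456	0.454308
PIK3C2B	C1S9200	0.000717	0.679158
PIK3C2B	C1S9222	0.000717	0.38177
PIK3C2B	C1S9250	0.001435	0.358232
PIK3C2B	C1S9266	0.002869	0.184476
PIK3C2B	C1S9267	0.002152	0.504508
PIK3C2B	C1S9306	0.000717	0.239692
PIK3C2B	C1S9320	0.000717	0.653693
PIK3C2B	C1S9333	0.000717	0.703217
PIK3C2B	C1S9346	0.000717	0.29823
PIK3C2B	C1S9373	0.000717	0.399922
PIK3C2B	C1S9391	0.000717	0.582382
PIK3C2B	C1S9423	0.000717	0.590111
PIK3C2B	C1S9432	0.010760	0.461306
PIK3C2B	C1S9445	0.000717	0.582247
PIK3C2B	C1S9446	0.000717	0.477664
PIK3C2B	C1S9449	0.000717	0.647146
PIK3C2B	C1S9455	0.002869	0.518095
PIK3C2B	C1S9457	0.000717	0.497112
PIK3C3	C18S2475	0.000717	0.695313
PIK3C3	C18S2492	0.017217	0.576351
PIK3R3	C1S2919	0.000717	0.414798
PRKCA	C17S4578	0.166428	0.39334
PRKCA	C17S4581	0.000717	0.129034
PRKCB1	C16S1894	0.000717	0.45754
PTK2	C8S4825	0.000717	0.0164796
PTK2	C8S4839	0.000717	0.142502
PTK2B	C8S886	0.000717	0.466067
PTK2B	C8S900	0.001435	0.111154
PTK2B	C8S909	0.001435	0.431062
RRAS	C19S4929	0.001435	0.34384
RRAS	C19S4937	0.001435	0.462103
SHC1	C1S7061	0.006456	0.206036
SOS2	C14S1381	0.000717	0.613801
SOS2	C14S1382	0.003587	0.633247
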
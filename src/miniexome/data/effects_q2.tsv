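gene	snp	maf	beta
BCHE	C3S4834	0.000717	0.232562
BCHE	C3S4836	0.000717	0.352589
BCHE	C3S4856	0.000717	0.311344
BCHE	C3S4859	0.002152	0.557489
BCHE	C3S4860	0.000717	0.339017
BCHE	C3S4862	0.000717	0.93321
BCHE	C3S4867	0.000717	0.67704
BCHE	C3S4869	0.000717	1.15994
BCHE	C3S4873	0.002869	0.588113
BCHE	C3S4874	0.000717	1.06857
BCHE	C3S4875	0.000717	1.15207
BCHE	C3S4876	0.000717	0.798247
BCHE	C3S4880	0.001435	0.164995
GCKR	C2S354	0.012195	0.396642
INSIG1	C7S5132	0.000717	0.0983783
INSIG1	C7S5133	0.000717	0.106056
INSIG1	C7S5144	0.000717	0.237783
LPL	C8S442	0.015782	0.490165
LPL	C8S476	0.000717	0.725673
LPL	C8S530	0.001435	0.800024
PDGFD	C11S5292	0.008608	0.60155
PDGFD	C11S5299	0.000717	0.823159
PDGFD	C11S5301	0.000717	0.982146
PDGFD	C11S5302	0.001435	0.814925
PLAT	C8S1741	0.003587	0.71858
PLAT	C8S1742	0.000717	0.891241
PLAT	C8S1758	0.001435	0.86814
PLAT	C8S1770	0.000717	0.58405
PLAT	C8S1772	0.001435	0.219187
PLAT	C8S1773	0.001435	0.515733
PLAT	C8S1799	0.005739	0.190653
PLAT	C8S1811	0.001435	0.0753783
RARB	C3S635	0.000717	0.653224
RARB	C3S679	0.005022	0.632142
SIRT1	C10S3048	0.002152	0.825893
SIRT1	C10S3050	0.002152	0.956865
SIRT1	C10S3058	0.000717	0.393157
SIRT1	C10S3092	0.000717	0.352589
SIRT1	C10S3093	0.000717	0.47264
SIRT1	C10S3107	0.000717	0.99946
SIRT1	C10S3108	0.000717	0.52925
SIRT1	C10S3109	0.000717	0.57047
SIRT1	C10S3110	0.002152	0.117719
SREBF1	C17S1007	0.002152	0.548739
SREBF1	C17S1009	0.000717	0.716057
SREBF1	C17S1024	0.004304	0.447239
SREBF1	C17S1030	0.000717	0.734055
SREBF1	C17S1043	0.004304	0.459494
SREBF1	C17S1045	0.003587	0.30998
SREBF1	C17S1046	0.002869	0.604567
SREBF1	C17S1048	0.001435	0.297328
SREBF1	C17S1055	0.001435	0.957889
SREBF1	C17S1056	0.000717	0.46384
VLDLR	C9S367	0.000717	0.510889
VLDLR	C9S376	0.002869	0.543897
VLDLR	C9S377	0.001435	1.20543
VLDLR	C9S391	0.000717	0.483147
VLDLR	C9S430	0.000717	0.677573
VLDLR	C9S443	0.001435	0.61953
VLDLR	C9S444	0.001435	0.901646
VLDLR	C9S497	0.000717	0.731422
VNN1	C6S5378	0.005739	0.466305
VNN1	C6S5380	0.170732	0.248606
VNN3	C6S5412	0.000717	0.551757
VNN3	C6S5426	0.032999	0.110779
VNN3	C6S5439	0.000717	0.127341
VNN3	C6S5441	0.098278	0.268411
VNN3	C6S5446	0.000717	0.528353
VNN3	C6S5448	0.000717	0.581462
VNN3	C6S5449	0.010043	0.680317
VWF	C12S181	0.000717	0.76848
VWF	C12S211	0.005739	0.337463
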
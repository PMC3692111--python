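target	template	pct_id	pct_cov	rmsd_memoir	rmsd_hhpred	rmsd_swissmodel
2Q7MC	2H8AA	10	57	4.07	3.63	3.76
2JMMA	2LHFA	13	62	3.85	3.85	5.29
3GIAA	3L1LA	15	93	3.97	4.20	4.81
3O0RB	3MK7A	18	92	3.18	2.64	2.91
1OGVM	2AXTa	19	59	2.60	5.06	3.39
2VL0A	3RHWA	22	93	2.61	2.58	2.64
3BRYA	3DWOX	23	84	4.25	3.67	3.55
2WIEA	2X2VA	27	80	1.31	1.47	1.31
1YC9A	3PIKA	27	89	1.35	2.16	1.35
2D57A	2W2EA	31	97	1.80	2.06	2.02
2HYDA	3B60A	34	94	2.31	2.97	2.33
1L0LD	1ZRTD	35	89	1.30	1.54	1.28
1EZVE	2FYNC	47	65	2.11	3.72	3.01
1M56C	1OCCC	48	99	1.10	2.33	2.04
2QKSA	3SYOA	50	90	2.72	2.58	3.15
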
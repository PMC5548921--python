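panel	marker	target	n_target_pos	n_marker_pos	n_double	printed_pct_of_target	printed_pct_of_marker
A	TAS1R3-GFP	CPLX2	80	56	18	22.5	32
A	TAS1R3-GFP	PCLO	98	48	48	48.9	100
A	TAS1R3-GFP	SEMA4A	98	65	55	56.1	84.6
A	TAS1R3-GFP	PLEXINB1	106	54	52	49	96.3
A	TAS1R3-GFP	CRMP2	92	58	49	53.2	84.5
A	TAS1R3-GFP	FES	219	138	123	56.1	89.1
B	5HT	CPLX2	183	174	173	94.5	99.4
B	5HT	PCLO	108	84	75	69.4	89.2
B	5HT	FES	130	39	16	12.3	41
B	5HT	SEMA4A	110	50	24	21.8	48
C	GAD1-GFP	PLEXINB1	175	111	40	22.8	36.0
C	GAD1-GFP	CRMP2	107	88	56	52.3	63.6
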
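gene_id	gene_name	marked_cell_type	avg_count_tas1r3	avg_count_type3	log2fc	fdr
Plcb2	phospholipase C, beta 2	Tas1r3	52005	2.2	-14.4	1.10E-103
Tas1r2	taste receptor, type 1, member 2	Tas1r3	3103.2	0.1	-14.8	1.10E-26
Tas1r3	taste receptor, type 1, member 3	Tas1r3	6619.5	48.4	-6.7	1.58E-05
Tas1r1	taste receptor, type 1, member 1	Tas1r3	1804.5	14.8	-6.4	7.14E-04
Trpm5	transient receptor potential cation channel, subfamily M, member 5	Tas1r3	22979	1.5	-13.7	2.33E-62
P2rx7	purinergic receptor P2X, ligand-gated ion channel, 7	Tas1r3	1624.7	30.8	-5.3	2.73E-03
Gna14	guanine nucleotide binding protein, alpha 14	Tas1r3	22803	26.9	-9.1	1.37E-08
Gng13	guanine nucleotide binding protein, gamma 13	Tas1r3	681.5	0.08	-12.3	8.42E-21
Chgb	chromogranin B	TypeIII	1.5	8288.3	12.1	8.38E-38
Chga	chromogranin A	TypeIII	4.7	8001.3	10.3	8.09E-21
Ncam1	neural cell adhesion molecule 1	TypeIII	30.4	16476.9	8.9	1.15E-26
Gad1	glutamate decarboxylase 1	TypeIII	2.5	33978.7	13.5	1.90E-64
Car4	carbonic anhydrase 4	TypeIII	11.3	9307	9.2	1.57E-10
Pkd2l1	polycystic kidney disease 2-like 1	TypeIII	4.5	28791.2	12.6	7.70E-158
Pkd1l3	polycystic kidney disease 1 like 3	TypeIII	23	24051.7	9.8	4.24E-30
Snap25	synaptosomal-associated protein 25	TypeIII	70.5	73176.5	9.9	1.51E-50
Cacna2d1	calcium channel, voltage-dependent, alpha2/delta subunit 1	TypeIII	11.5	26660.5	11.0	6.09E-42
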
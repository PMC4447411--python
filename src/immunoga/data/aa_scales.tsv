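# Per-residue amino-acid property scales bundled with immunoga.
# Sources: Kyte & Doolittle (1982) hydropathy; Hopp & Woods (1981)
# hydrophilicity; side-chain masses from residue formula weights;
# Grantham (1974) polarity, volume and composition; net side-chain
# charge at pH 7; residue isoelectric points; Chothia (1976) tripeptide
# accessible surface areas; Chou & Fasman (1978) helix/sheet/turn
# propensities.  Columns follow the alphabetical one-letter order.
scale_id	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
hydropathy_kd	1.8	2.5	-3.5	-3.5	2.8	-0.4	-3.2	4.5	-3.9	3.8	1.9	-3.5	-1.6	-3.5	-4.5	-0.8	-0.7	4.2	-0.9	-1.3
hydrophilicity_hw	-0.5	-1.0	3.0	3.0	-2.5	0.0	-0.5	-1.8	3.0	-1.8	-1.3	0.2	0.0	0.2	3.0	0.3	-0.4	-1.5	-3.4	-2.3
side_chain_mass	15.03	47.10	59.04	73.07	91.13	1.01	81.10	57.11	72.13	57.11	75.15	58.06	42.08	72.09	100.14	31.03	45.06	43.09	130.17	107.13
polarity_grantham	8.1	5.5	13.0	12.3	5.2	9.0	10.4	5.2	11.3	4.9	5.7	11.6	8.0	10.5	10.5	9.2	8.6	5.9	5.4	6.2
volume_grantham	31	55	54	83	132	3	96	111	119	111	105	56	32.5	85	124	32	61	84	170	136
composition_grantham	0	2.75	1.38	0.92	0	0.74	0.58	0	0.33	0	0	1.33	0.39	0.89	0.65	1.42	0.71	0	0.13	0.20
charge_ph7	0	0	-1	-1	0	0	0.1	0	1	0	0	0	0	0	1	0	0	0	0	0
isoelectric_point	6.00	5.07	2.77	3.22	5.48	5.97	7.59	6.02	9.74	5.98	5.74	5.41	6.30	5.65	10.76	5.68	5.60	5.96	5.89	5.66
asa_chothia	115	135	150	190	210	75	195	175	200	170	185	160	145	180	225	115	140	155	255	230
helix_cf	1.42	0.70	1.01	1.51	1.13	0.57	1.00	1.08	1.16	1.21	1.45	0.67	0.57	1.11	0.98	0.77	0.83	1.06	1.08	0.69
sheet_cf	0.83	1.19	0.54	0.37	1.38	0.75	0.87	1.60	0.74	1.30	1.05	0.89	0.55	1.10	0.93	0.75	1.19	1.70	1.37	1.47
turn_cf	0.66	1.19	1.46	0.74	0.60	1.56	0.95	0.47	1.01	0.59	0.60	1.56	1.52	0.98	0.95	1.43	0.96	0.50	0.96	1.14
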
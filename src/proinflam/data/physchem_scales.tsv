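residue	amphipathicity	hydrophobicity	pI	bulkiness	hydrophilicity	net_hydrogen	steric_hindrance	charge	hydropathy	molecular_weight
A	0.00	0.62	6.00	11.50	-0.50	0	0.52	0.0	1.8	71.03711
C	0.00	0.29	5.07	13.46	-1.00	1	0.62	0.0	2.5	103.00919
D	0.00	-0.90	2.77	11.68	3.00	-4	0.76	-1.0	-3.5	115.02694
E	1.27	-0.74	3.22	13.57	3.00	-4	0.68	-1.0	-3.5	129.04259
F	0.00	1.19	5.48	19.80	-2.50	0	0.70	0.0	2.8	147.06841
G	0.00	0.48	5.97	3.40	0.00	0	0.00	0.0	-0.4	57.02146
H	1.45	-0.40	7.59	13.69	-0.50	1	0.70	0.1	-3.2	137.05891
I	0.00	1.38	6.02	21.40	-1.80	0	1.02	0.0	4.5	113.08406
K	3.67	-1.50	9.74	15.71	3.00	2	0.68	1.0	-3.9	128.09496
L	0.00	1.06	5.98	21.40	-1.80	0	0.98	0.0	3.8	113.08406
M	0.00	0.64	5.74	16.25	-1.30	0	0.78	0.0	1.9	131.04049
N	0.00	-0.78	5.41	12.82	0.20	0	0.76	0.0	-3.5	114.04293
P	0.00	0.12	6.30	17.43	0.00	0	0.36	0.0	-1.6	97.05276
Q	1.25	-0.85	5.65	14.45	0.20	0	0.68	0.0	-3.5	128.05858
R	2.45	-2.53	10.76	14.28	3.00	4	0.68	1.0	-4.5	156.10111
S	0.00	-0.18	5.68	9.47	0.30	0	0.53	0.0	-0.8	87.03203
T	0.00	-0.05	5.60	15.77	-0.40	0	0.70	0.0	-0.7	101.04768
V	0.00	1.08	5.96	21.57	-1.50	0	0.76	0.0	4.2	99.06841
W	6.93	0.81	5.89	21.67	-3.40	1	0.70	0.0	-0.9	186.07931
Y	5.06	0.26	5.66	18.03	-2.30	0	0.70	0.0	-1.3	163.06333
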
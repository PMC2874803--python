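# Ten physicochemical values per residue type, assembled from standard scales:
# heavy-atom count; signed unit charge count; side-chain H-bond donor+acceptor
# capacity; Kyte-Doolittle hydrophobicity; Hopp-Woods hydrophilicity; helix
# propensity (Chou-Fasman, shipped default for the propensity slot); free
# amino-acid isoelectric point; residue mass (Da); approximate expected
# contact number within a 14 A sphere (Enc); electron-ion interaction
# potential (EIIP). Override any cell with a user table.
aa	n_atoms	charge	h_bonds	hydrophobicity	hydrophilicity	propensity	isoelectric_point	mass	Enc	eiip
ALA	5	0	0	1.8	-0.5	1.42	6.00	71.08	16.0	0.0373
ARG	11	1	4	-4.5	3.0	0.98	10.76	156.19	14.0	0.0959
ASN	8	0	4	-3.5	0.2	0.67	5.41	114.10	13.8	0.0036
ASP	8	-1	4	-3.5	3.0	1.01	2.77	115.09	13.6	0.1263
CYS	6	0	1	2.5	-1.0	0.70	5.07	103.14	18.0	0.0829
GLN	9	0	4	-3.5	0.2	1.11	5.65	128.13	13.5	0.0761
GLU	9	-1	4	-3.5	3.0	1.51	3.22	129.12	13.0	0.0058
GLY	4	0	0	-0.4	0.0	0.57	5.97	57.05	15.0	0.0050
HIS	10	1	2	-3.2	-0.5	1.00	7.59	137.14	15.8	0.0242
ILE	8	0	0	4.5	-1.8	1.08	6.02	113.16	18.8	0.0000
LEU	8	0	0	3.8	-1.8	1.21	5.98	113.16	18.5	0.0000
LYS	9	1	2	-3.9	3.0	1.16	9.74	128.17	12.5	0.0371
MET	8	0	1	1.9	-1.3	1.45	5.74	131.20	18.5	0.0823
PHE	11	0	0	2.8	-2.5	1.13	5.48	147.18	19.0	0.0946
PRO	7	0	0	-1.6	0.0	0.57	6.30	97.12	13.6	0.0198
SER	6	0	3	-0.8	0.3	0.77	5.68	87.08	14.6	0.0829
THR	7	0	3	-0.7	-0.4	0.83	5.60	101.10	15.1	0.0941
TRP	14	0	1	-0.9	-3.4	1.08	5.89	186.21	18.1	0.0548
TYR	12	0	2	-1.3	-2.3	0.69	5.66	163.18	16.8	0.0516
VAL	7	0	0	4.2	-1.5	1.06	5.96	99.13	18.2	0.0057
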
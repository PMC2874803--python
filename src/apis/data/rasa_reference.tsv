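# Maximum ASA reference (A^2) per residue type and attribute class,
# computed by this package's Shrake-Rupley engine on ideal isolated
# residue conformations (CCD geometry, heavy atoms, probe 1.4 A,
# 960 lattice points). GLY side_chain uses CA as pseudo-side-chain.
# Regenerate with scripts/generate_reference_data.py
aa	total	backbone	side_chain	polar	non_polar
ALA	205.28	143.39	61.89	92.70	112.59
ARG	336.98	134.43	202.55	207.29	129.69
ASN	257.19	129.11	128.08	176.55	80.63
ASP	256.41	129.22	127.19	174.77	81.64
CYS	239.05	134.61	104.44	86.43	78.50
GLN	287.33	136.81	150.52	185.57	101.77
GLU	287.23	136.78	150.45	184.46	102.77
GLY	182.60	182.60	43.78	97.82	84.79
HIS	293.49	132.96	160.53	141.53	151.96
ILE	271.72	127.31	144.41	87.68	184.04
LEU	275.63	129.58	146.05	86.43	189.20
LYS	305.24	136.59	168.65	144.98	160.26
MET	295.62	136.89	158.73	88.59	160.39
PHE	310.47	129.33	181.14	82.66	227.81
PRO	236.39	116.88	119.50	67.07	169.32
SER	223.17	138.84	84.33	139.39	83.78
THR	240.57	129.53	111.03	119.68	120.89
TRP	351.69	127.69	224.00	109.66	242.03
TYR	326.86	128.03	198.83	133.89	192.97
VAL	243.78	126.16	117.62	78.36	165.42
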
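case_no	protein_change	mutation_type	exonuclease_domain	nonsyn_snv_count	classification
1	P286R	missense	yes	9515	pole_category
2	P286R	missense	yes	7351	pole_category
3	P286R	missense	yes	3963	pole_category
4	Y1813C	missense	no	3385	common_hypermutator
5	P286R	missense	yes	3344	pole_category
6	P286R	missense	yes	2847	pole_category
7	F367C	missense	yes	2632	pole_category
8	P286R	missense	yes	2606	pole_category
9	P286R	missense	yes	1870	pole_category
10	V411L	missense	yes	1859	pole_category
11	P1207S, V1218I	missense	no	1782	common_hypermutator
12	S297Y	missense	yes	1698	pole_category
13	E767D	missense	no	1495	common_hypermutator
14	E1199D	missense	no	1289	common_hypermutator
15	K879E, R1626H	missense	no	1274	common_hypermutator
16	K391T	missense	yes	1120	common_hypermutator
17	T2049A	missense	no	1110	common_hypermutator
18	Q196*	nonsense	yes	1041	common_hypermutator
19	R47W	missense	no	723	common_hypermutator
20	R1289C	missense	no	188	nonhypermutator
21	T1904A	missense	no	157	nonhypermutator
22	V533M	missense	no	119	nonhypermutator
23	D1131E	missense	no	97	nonhypermutator
24	K1942*	nonsense	no	60	nonhypermutator
25	Q125H	missense	yes	51	nonhypermutator
26	A1200T	missense	no	45	nonhypermutator
27	R259H	missense	yes	36	nonhypermutator
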
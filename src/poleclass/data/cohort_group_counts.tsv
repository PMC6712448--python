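variable	level	nonhypermutator	common_hypermutator	pole_category
sex	man	494	29	9
sex	woman	349	28	1
location	right	245	41	4
location	left	598	16	6
histology	well_or_mod	805	41	8
histology	por_or_muc	38	16	2
pT_stage	Tis-T2	190	13	2
pT_stage	T3-T4	653	44	8
pStage	0-II	392	38	8
pStage	III-IV	451	19	2
lymphatic_invasion	yes	432	35	4
lymphatic_invasion	no	411	22	6
vessel_invasion	yes	559	28	5
vessel_invasion	no	284	29	5
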
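index	name	hemisphere	lobe
0	lh.bankssts	left	temporal
1	lh.caudalanteriorcingulate	left	limbic
2	lh.caudalmiddlefrontal	left	fronto-insular
3	lh.cuneus	left	occipital
4	lh.entorhinal	left	limbic
5	lh.fusiform	left	temporal
6	lh.inferiorparietal	left	parietal
7	lh.inferiortemporal	left	temporal
8	lh.isthmuscingulate	left	limbic
9	lh.lateraloccipital	left	occipital
10	lh.lateralorbitofrontal	left	fronto-insular
11	lh.lingual	left	occipital
12	lh.medialorbitofrontal	left	fronto-insular
13	lh.middletemporal	left	temporal
14	lh.parahippocampal	left	limbic
15	lh.paracentral	left	sensorimotor
16	lh.parsopercularis	left	fronto-insular
17	lh.parsorbitalis	left	fronto-insular
18	lh.parstriangularis	left	fronto-insular
19	lh.pericalcarine	left	occipital
20	lh.postcentral	left	sensorimotor
21	lh.posteriorcingulate	left	limbic
22	lh.precentral	left	sensorimotor
23	lh.precuneus	left	parietal
24	lh.rostralanteriorcingulate	left	limbic
25	lh.rostralmiddlefrontal	left	fronto-insular
26	lh.superiorfrontal	left	fronto-insular
27	lh.superiorparietal	left	parietal
28	lh.superiortemporal	left	temporal
29	lh.supramarginal	left	parietal
30	lh.frontalpole	left	fronto-insular
31	lh.temporalpole	left	temporal
32	lh.transversetemporal	left	temporal
33	lh.insula	left	fronto-insular
34	rh.bankssts	right	temporal
35	rh.caudalanteriorcingulate	right	limbic
36	rh.caudalmiddlefrontal	right	fronto-insular
37	rh.cuneus	right	occipital
38	rh.entorhinal	right	limbic
39	rh.fusiform	right	temporal
40	rh.inferiorparietal	right	parietal
41	rh.inferiortemporal	right	temporal
42	rh.isthmuscingulate	right	limbic
43	rh.lateraloccipital	right	occipital
44	rh.lateralorbitofrontal	right	fronto-insular
45	rh.lingual	right	occipital
46	rh.medialorbitofrontal	right	fronto-insular
47	rh.middletemporal	right	temporal
48	rh.parahippocampal	right	limbic
49	rh.paracentral	right	sensorimotor
50	rh.parsopercularis	right	fronto-insular
51	rh.parsorbitalis	right	fronto-insular
52	rh.parstriangularis	right	fronto-insular
53	rh.pericalcarine	right	occipital
54	rh.postcentral	right	sensorimotor
55	rh.posteriorcingulate	right	limbic
56	rh.precentral	right	sensorimotor
57	rh.precuneus	right	parietal
58	rh.rostralanteriorcingulate	right	limbic
59	rh.rostralmiddlefrontal	right	fronto-insular
60	rh.superiorfrontal	right	fronto-insular
61	rh.superiorparietal	right	parietal
62	rh.superiortemporal	right	temporal
63	rh.supramarginal	right	parietal
64	rh.frontalpole	right	fronto-insular
65	rh.temporalpole	right	temporal
66	rh.transversetemporal	right	temporal
67	rh.insula	right	fronto-insular
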
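mating	parent_code	role	maturity_group	protein	oil	accession	name	origin
1	P1001	female	000	529	151	PI 153296	V-4	Belgium
2	P1002	female	000	504	158	PI 189963	Geant Vert	France
3	P1003	female	000	522	155	PI 548399	Pando	South Korea
4	P1004	female	000	477	156	PI 372423	Ronset 4	France
5	P1005	female	000	512	157	FC 30687	Kosodiguri Ext Early	Japan
6	P1006	female	000	511	158	PI 153293	N-34	Belgium
7	P1007	female	000	478	161	PI 372412	Hercumft	Germany
8	P1009	female	000	522	159	PI 548414	Sioux	Japan
	P1021M	male	000	430	199	PI 567787	OAC Vision	Canada
9	P1022	female	00	507	158	PI 153302	V-16	Belgium
10	P1023	female	00	526	157	PI 159764		South Korea
11	P1024	female	00	485	164	PI 438415	Ronest 4	France
12	P1025	female	00	508	147	PI 153301	V-14	Belgium
13	P1026	female	00	489	173	PI 189880	Bitterhof	Germany
14	P1027	female	00	510	148	PI 153297	V-6	Belgium
15	P2211	female	00				HHP	Illinois
16	P2212	female	00				AC Proteus	Canada
17	P2213	female	00				AC Proteina	Canada
	P1038M	male	00	415	185	PI 602897	Jim	North Dakota
18	P1039	female	0	480	144	PI 427138	Choseng No. 1	South Korea
19	P1040	female	0	488	195	PI 261469	Wasedaizu No. 1	Japan
20	P1041	female	0	485	177	PI 181571	No. 58	Japan
21	P1042	female	0	483	150	PI 424148	Shirome	South Korea
22	P1043	female	0	473	156	PI 423954	Shirome	Japan
23	P1044	female	0	494	160	PI 154196	No. 51	Netherlands
	P1053M	male	0	403	196	PI 602594	MN0301	Minnesota
24	P1054	female	I	484	155	PI 437088A	DV-147	Russian Federation (Far East)
25	P1055	female	I	514	144	PI 423949	Saikai 20	Japan
26	P1056	female	I	495	141	PI 427141	Seuhae No. 20	South Korea
27	P1057	female	I	482	138	PI 437716A	Sjuj-dja-pyn-da-do	China
28	P1058	female	I	489	149	PI 423942	Saikai 1	Japan
	P1074M	male	I			PI 602593	MN1301	Minnesota
29	P1075	female	II	499	157	PI 423948A	Saikai 18	Japan
30	P1076	female	II	482	154	PI 437112A	VIR 249	Russian Federation (Far East)
31	P1098	female	II	484	191	PI 548608	Provar	Iowa
	P1106M	male	II	382	195	PI 597386	Dwight	Illinois
32	P1107	female	III	504	132	PI 445845	Szu yueh pa	China
33	P1108	female	III	494	167	PI 398516	KAERI-GNT 310-1	South Korea
34	P1109	female	III	477	170	PI 91725-4	Akazu	South Korea
35	P1110	female	III	493	165	PI 340011		South Korea
36	P1111	female	III	478	162	PI 243532	Kariho-takiya	Japan
37	P1113	female	III	497	168	PI 408138C	KAS 640-7	South Korea
38	P1121	female	III	494	177	PI 398672	KAERI-GNT 301-1	South Korea
39	P1122	female	III	484	184	PI 360843	Oshimashirome	Japan
	P1137M	male	III	411	194	PI 597387	Pana	Illinois
40	P1138	female	IV	479	157	PI 253666A	No. 17	China
41	P1139	female	IV	507	151	PI 407788A	ORD 8113	South Korea
42	P1140	female	IV	493	155	PI 424286	KAS 239-4	South Korea
43	P1142	female	IV	488	166	PI 407877B	KAERI 511-11	South Korea
44	P1143	female	IV	488	158	PI 398704	KAS 330-9-1	South Korea
45	P1145	female	IV	491	160	PI 398970	KLS 630-1	South Korea
46	P1146	female	IV	493	159	PI 407823		South Korea
47	P1152	female	IV	492	161	PI 407773B	KAS 330-9-2	South Korea
	P1181M	male	IV	424	180	PI 606748	Rend	Illinois
48	P1183	female	V	476	195	PI 458256	KAS 578-1	South Korea
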
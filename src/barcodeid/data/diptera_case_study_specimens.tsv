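family	species	country	locality	process_id	barcode_hap	long_hap	sim_proc12	sim_proc3	sim_proc4	sim_proc5	tie_proc12	tie_proc3
Calliphoridae	Calliphora vicina	Belgium	Saint-Gilles/Sint-Gillis	NICC001-13	1	1	99.72	99.83	99.54	99.03	1	1
Calliphoridae	Calliphora vicina	Belgium	Schaerbeek/Schaarbeek	NICC002-13	2	na	100	100	99.85	na	1	1
Calliphoridae	Calliphora vicina	Belgium	Andrimont	NICC003-13	2	2	100	100	99.85	99.05	1	1
Calliphoridae	Calliphora vicina	Belgium	Hastiere	NICC004-13	2	3	100	100	99.85	99.23	1	1
Calliphoridae	Calliphora vicina	Belgium	Humbeek	NICC005-13	2	4	100	100	99.85	99.16	1	1
Calliphoridae	Calliphora vicina	Belgium	Ixelles/Elsene	NICC006-13	3	5	99.72	99.83	99.54	+	1	1
Calliphoridae	Calliphora vicina	Belgium	Auderghem/Oudergem	NICC007-13	2	3	100	100	99.85	99.23	1	1
Calliphoridae	Calliphora vicina	Belgium	Lier	NICC008-13	4	na	100	100	99.85	na	1	1
Calliphoridae	Calliphora vicina	Belgium	Gent	NICC009-13	5	6	99.86	100	99.7	+	1	1
Calliphoridae	Calliphora vicina	Belgium	Saintes	NICC010-13	6	7	99.86	99.6	99.7	99.1	1	1
Calliphoridae	Calliphora vicina	Belgium	Bruxelles/Brussel	NICC011-13	2	3	100	100	99.85	99.23	1	1
Calliphoridae	Calliphora vicina	Belgium	Hastiere	NICC012-13	7	8	99.86	99.86	99.7	99.03	1	1
Calliphoridae	Calliphora vicina	Belgium	Auderghem/Oudergem	NICC013-13	8	9	100	100	100	99.1	1	1
Calliphoridae	Calliphora vicina	Belgium	Schaerbeek/Schaarbeek	NICC014-13	9	10	99.72	99.83	99.54	99.03	1	1
Calliphoridae	Calliphora vomitoria	Belgium	Toernich	NICC015-13	10	na	100	100	99.09	na	0	0
Calliphoridae	Calliphora vomitoria	Belgium	Hastiere	NICC016-13	10	11	100	100	99.09	99.02	0	0
Calliphoridae	Calliphora vomitoria	Belgium	Andrimont	NICC017-13	11	12	99.58	100	99.38	+	0	0
Calliphoridae	Calliphora vomitoria	Belgium	Schaerbeek/Schaarbeek	NICC018-13	10	11	100	100	99.09	99.02	0	0
Calliphoridae	Calliphora vomitoria	Belgium	Genk	NICC019-13	10	11	100	100	99.09	99.02	0	0
Calliphoridae	Calliphora vomitoria	Belgium	Laeken/Laken	NICC020-13	10	13	100	100	99.09	+	0	0
Calliphoridae	Calliphora vomitoria	Belgium	Liege	NICC021-13	10	11	100	100	99.09	99.02	0	0
Calliphoridae	Calliphora vomitoria	Belgium	Saintes	NICC022-13	10	14	100	100	99.09	+	0	0
Calliphoridae	Calliphora vomitoria	Belgium	Steendorp	NICC023-13	10	11	100	100	99.09	99.02	0	0
Calliphoridae	Calliphora vomitoria	Belgium	Gent	NICC024-13	10	11	100	100	99.09	99.02	0	0
Calliphoridae	Calliphora vomitoria	Belgium	Hastiere	NICC025-13	10	na	100	100	99.09	na	0	0
Calliphoridae	Calliphora vomitoria	Belgium	Schaerbeek/Schaarbeek	NICC026-13	10	11	100	100	99.09	99.02	0	0
Calliphoridae	Calliphora vomitoria	Belgium	Genk	NICC027-13	10	11	100	100	99.09	99.02	0	0
Calliphoridae	Calliphora vomitoria	Belgium	Sint-Laureins	NICC028-13	10	11	100	100	99.09	99.02	0	0
Calliphoridae	Calliphora vomitoria	Belgium	Schoonaarde	NICC029-13	12	15	99.86	100	98.94	+	0	0
Calliphoridae	Calliphora vomitoria	Belgium	Antwerpen	NICC030-13	10	na	100	100	99.09	na	0	0
Calliphoridae	Chrysomya albiceps	France	St Pourcain/Sioule	NICC031-13	13	16	100	100		99.29	0	0
Calliphoridae	Chrysomya albiceps	France	St Pourcain/Sioule	NICC032-13	14	na	100	100		na	0	0
Calliphoridae	Chrysomya albiceps	France	St Pourcain/Sioule	NICC033-13	15	17	99.86	100		99.23	0	0
Calliphoridae	Chrysomya albiceps	France	St Pourcain/Sioule	NICC034-13	13	16	100	100		99.29	0	0
Calliphoridae	Chrysomya albiceps	France	St Pourcain/Sioule	NICC035-13	14	na	100	100		na	0	0
Calliphoridae	Chrysomya albiceps	France	Sarreguemines	NICC036-13	13	16	100	100		99.29	0	0
Calliphoridae	Chrysomya albiceps	Belgium	Meerdaalwoud	NICC037-13	16	na	99.86	100		na	0	0
Calliphoridae	Cynomya mortuorum	Belgium		NICC038-13	17	18	99.73	100			0	0
Calliphoridae	Lucilia ampullacea	Belgium	Flemalle	LUCIL001-12	18	19	100	100		99.23	0	0
Calliphoridae	Lucilia ampullacea	Belgium	Flemalle	LUCIL002-12	19	20	99.86	99.86		99.1	0	0
Calliphoridae	Lucilia sericata	Belgium	Hastiere	LUCIL061-12	20	21	99.86	100	100	99.23	0	0
Calliphoridae	Lucilia sericata	Belgium	Auderghem/Oudergem	LUCIL062-12	21	na	100	100	100	na	0	1
Calliphoridae	Lucilia sericata	Belgium	Gent	LUCIL063-12	22	22	100	100	100	99.16	0	1
Calliphoridae	Lucilia sericata	Belgium	Lier	LUCIL064-12	22	23	100	100	100	99.23	0	1
Calliphoridae	Lucilia sericata	France	Le Soler	LUCIL065-12	22	24	100	100	100	99.29	0	1
Calliphoridae	Lucilia sericata	France	Le Soler	LUCIL066-12	23	25	99.86	100	100	99.23	0	1
Calliphoridae	Lucilia sericata	Belgium		LUCIL067-12	22	24	100	100	100	99.29	0	1
Calliphoridae	Lucilia sericata	Belgium	Auderghem/Oudergem	LUCIL068-12	24	26	100	100	100	99.23	0	0
Calliphoridae	Lucilia sericata	Belgium	Schaerbeek/Schaarbeek	LUCIL069-12	25	27	100	100	100	99.16	0	1
Calliphoridae	Lucilia sericata	Belgium	Genk	LUCIL070-12	22	24	100	100	100	99.29	0	1
Calliphoridae	Lucilia sericata	Belgium	Genk	LUCIL071-12	26	28	99.86	100	100	99.23	0	1
Calliphoridae	Lucilia sericata	France		LUCIL072-12	22	29	100	100	100	99.23	0	1
Calliphoridae	Lucilia sericata	France		LUCIL073-12	22	29	100	100	100	99.23	0	1
Calliphoridae	Lucilia sericata	France		LUCIL074-12	22	29	100	100	100	99.23	0	1
Calliphoridae	Lucilia sericata	France		LUCIL075-12	22	29	100	100	100	na	0	1
Calliphoridae	Lucilia sericata	France		LUCIL076-12	22	29	100	100	100	99.23	0	1
Calliphoridae	Protophormia terraenovae	Belgium	Andrimont	NICC056-13	27	na	99.86	100	99.7	na	0	0
Calliphoridae	Protophormia terraenovae	Belgium	Auderghem/Oudergem	NICC057-13	27	na	99.86	100	99.7	na	0	0
Calliphoridae	Protophormia terraenovae	Belgium	Andrimont	NICC058-13	28	na	100	100	99.85	na	0	0
Calliphoridae	Protophormia terraenovae	Belgium	Andrimont	NICC059-13	27	na	99.86	100	99.7	na	0	0
Calliphoridae	Protophormia terraenovae	Belgium	Andrimont	NICC060-13	27	na	99.86	100	99.7	na	0	0
Calliphoridae	Protophormia terraenovae	Belgium	Andrimont	NICC061-13	29	na	100	100	99.85	na	0	0
Calliphoridae	Protophormia terraenovae	Belgium	Andrimont	NICC062-13	28	na	100	100	99.85	na	0	0
Calliphoridae	Protophormia terraenovae	Belgium	Andrimont	NICC063-13	30	na	100	100	100	na	0	0
Calliphoridae	Protophormia terraenovae	Belgium	Andrimont	NICC064-13	28	na	100	100	99.85	na	0	0
Calliphoridae	Protophormia terraenovae	Belgium	Andrimont	NICC065-13	31	na	99.72	100	99.85	na	0	0
Calliphoridae	Protophormia terraenovae	Belgium	Andrimont	NICC066-13	28	na	100	100	99.85	na	0	0
Calliphoridae	Protophormia terraenovae	Belgium	Auderghem/Oudergem	NICC067-13	27	na	99.86	100	99.7	na	0	0
Fanniidae	Fannia sp1	Belgium	Soignes/Zonien forest	NICC040-13	32	30		100			0	0
Fanniidae	Fannia sp2	Belgium	Soignes/Zonien forest	NICC041-13	33	31		100			0	0
Fanniidae	Fannia sp3	Belgium	Soignes/Zonien forest	NICC042-13	34	32					0	0
Muscidae	Eudasyphora cyanella	Belgium	Soignes/Zonien forest	NICC039-13	35	33	100	100			0	0
Muscidae	Musca autumnalis	Belgium	Soignes/Zonien forest	NICC043-13	36	34	100	100			0	0
Muscidae	Muscina levida	Belgium	Pecq	NICC044-13	37	35	100	100	100		0	0
Muscidae	Muscina levida	Belgium	Pecq	NICC045-13	38	36	99.85	100	99.85		0	0
Muscidae	Muscina levida	Belgium	Pecq	NICC046-13	37	37	100	100	100		0	0
Muscidae	Muscina levida	Belgium	Pecq	NICC047-13	37	35	100	100	100		0	0
Muscidae	Muscina levida	Belgium	Soignes/Zonien forest	NICC048-13	37	38	100	100	100		0	0
Muscidae	Muscina prolapsa	Belgium	Soignes/Zonien forest	NICC049-13	39	39		99.85			0	0
Muscidae	Muscina prolapsa	Belgium	Soignes/Zonien forest	NICC050-13	39	na		99.85		na	0	0
Muscidae	Muscina prolapsa	Belgium	Saint-Gilles/Sint-Gillis	NICC051-13	40	40		100			0	0
Muscidae	Muscina prolapsa	Belgium	Saint-Gilles/Sint-Gillis	NICC052-13	40	40		100			0	0
Muscidae	Muscina prolapsa	Belgium	Soignes/Zonien forest	NICC053-13	40	na		100		na	0	0
Muscidae	Neomyia cornicina	Belgium	Soignes/Zonien forest	NICC054-13	41	41					0	0
Muscidae	Polietes lardarius	Belgium	Soignes/Zonien forest	NICC055-13	42	42	99.84	99.85			0	0
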
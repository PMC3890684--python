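species	n_barcode_haps	n_long_haps	proc12	proc3	proc4	proc5	incorrect_proc12	incorrect_proc3	incorrect_proc4	incorrect_proc5
Calliphora vicina	9	10	ok_plus_tie	ok_plus_tie	ok	ok	Calliphora croceipalpis;Musca domestica	Calliphora croceipalpis;Musca domestica
Calliphora vomitoria	3	5	ok	ok	ok	ok
Chrysomya albiceps	4	2	ok	ok	none	ok
Lucilia ampullacea	2	2	ok_plus	ok_plus	none	ok	Lucilia porphyrina;Chrysomya megacephala	Chrysomya megacephala
Lucilia sericata	7	9	ok_plus	ok_plus_tie	ok_plus	ok_plus	Lucilia cuprina	Lucilia cuprina	Lucilia cuprina	Lucilia cuprina
Protophormia terraenovae	5	0	ok	ok_plus	ok	na		Protophormia uralensis
Fannia sp1	1	1	none	wrong_ambiguous	none	none		Fannia pallitibia;Fannia lustrator
Fannia sp2	1	1	none	wrong	none	none		Fannia manicata
Fannia sp3	1	1	none	none	none	none
Cynomya mortuorum	1	1	ok	ok_plus	none	none		Cynomya cadaverina
Eudasyphora cyanella	1	1	ok	ok	none	none
Musca autumnalis	1	1	ok	ok	none	none
Muscina levida	2	4	ok	ok	ok	none
Muscina prolapsa	2	2	none	ok	none	none
Neomyia cornicina	1	1	none	none	none	none
Polietes lardarius	1	1	ok	ok	none	none
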
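population	ecotype_flag	sole_ha	translocation_group	shared_history_group	expected_type	expected_unit
a'Bhaid-Luachraich	0	0	NA	NA	MU	a'Bhaid-Luachraich
a'Garbh-bhaid Mor	0	0	NA	NA	MU	a'Garbh-bhaid Mor
Ard Achadh	0	0	NA	NA	MU	Ard Achadh
Arkaig (Benthivore)	1	0	NA	NA	ESU	Arkaig (Benthivore)
Arkaig (Planktivore)	1	0	NA	NA	ESU	Arkaig (Planktivore)
Awe (Benthivore)	1	0	NA	NA	ESU	Awe (Benthivore)
Awe (Planktivore)	1	0	NA	NA	ESU	Awe (Planktivore)
Braig horrisdale	0	0	NA	NA	MU	Braig horrisdale
Brora	0	0	NA	NA	MU	Brora
Bruicheach	0	1	NA	NA	ESU	Bruicheach
Calder	0	0	NA	NA	MU	Calder
Coulin	0	0	NA	coulin_dughaill_fannich_uaine	ESU	coulin_dughaill_fannich_uaine
Damh	0	0	NA	NA	MU	Damh
Doine	1	0	NA	NA	ESU	Doine
Doon	0	1	doon_talla	NA	ESU	doon_talla
Dubh	0	0	NA	NA	MU	Dubh
Dughaill (Benthivore)	1	0	NA	NA	ESU	Dughaill (Benthivore)
Dughaill (Planktivore)	1	0	NA	coulin_dughaill_fannich_uaine	ESU	coulin_dughaill_fannich_uaine
Duntelchaig	0	0	NA	NA	MU	Duntelchaig
Earn	0	1	NA	NA	ESU	Earn
Eck	0	1	NA	NA	ESU	Eck
Ericht (Benthivore)	1	0	NA	NA	ESU	Ericht (Benthivore)
Ericht (Planktivore)	1	0	NA	ericht_garry	ESU	ericht_garry
Fannich	0	0	NA	coulin_dughaill_fannich_uaine	ESU	coulin_dughaill_fannich_uaine
Garry	0	0	NA	ericht_garry	ESU	ericht_garry
Insh	0	0	NA	NA	MU	Insh
Laggan	0	0	NA	laggan_treig	MU	laggan_treig
Langavat	0	0	NA	NA	MU	Langavat
Lee	0	1	NA	NA	ESU	Lee
Loch	0	0	NA	NA	MU	Loch
Lochy (Benthivore)	1	0	NA	NA	ESU	Lochy (Benthivore)
Lochy (Planktivore)	1	0	NA	NA	ESU	Lochy (Planktivore)
Lubnaig	1	0	NA	NA	ESU	Lubnaig
Luichart	0	0	NA	NA	MU	Luichart
Maree	1	0	NA	NA	ESU	Maree
Meadie	0	0	NA	NA	MU	Meadie
Mealt	0	0	NA	NA	MU	Mealt
Merkland	1	0	NA	NA	ESU	Merkland
More	1	0	NA	NA	ESU	More
Morie	0	0	NA	NA	MU	Morie
Nam Brac	0	0	NA	NA	MU	Nam Brac
naSealga (Benthivore)	1	0	NA	NA	ESU	naSealga (Benthivore)
naSealga (Planktivore)	1	0	NA	NA	ESU	naSealga (Planktivore)
Naver	0	0	NA	NA	MU	Naver
Osgaig	0	0	NA	NA	MU	Osgaig
Rannoch (Benthivore)	1	0	NA	NA	ESU	Rannoch (Benthivore)
Rannoch (Piscivore)	1	0	NA	NA	ESU	Rannoch (Piscivore)
Rannoch (Planktivore)	1	0	NA	NA	ESU	Rannoch (Planktivore)
Seil	0	0	NA	NA	MU	Seil
Shin	1	0	NA	NA	ESU	Shin
Stack	1	0	NA	NA	ESU	Stack
Talla	0	0	doon_talla	NA	ESU	doon_talla
Tarff	0	0	NA	NA	MU	Tarff
Tay (Benthivore)	1	0	NA	NA	ESU	Tay (Benthivore)
Tay (Planktivore)	1	0	NA	NA	ESU	Tay (Planktivore)
Treig	0	0	NA	laggan_treig	MU	laggan_treig
Tummel	0	0	NA	NA	MU	Tummel
Uaine	0	0	NA	coulin_dughaill_fannich_uaine	ESU	coulin_dughaill_fannich_uaine
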
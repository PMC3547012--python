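sample_id	tissue	source	location	species	haplotype	notes
AIM 46/10 E.c?	bone	midden	Taupo	A. didiformis	A1	Whakamoenga Cave
AIM AR158	bone	midden	Coromandel	D. novaezealandiae	D13	Onemana
AIM AR2964	bone	midden	Coromandel	D. novaezealandiae	D3	Hot Water Beach
AIM AR5876	bone	midden	Taupo	E. curtus	E1	Whakamoenga Cave
AIM t12/500 n53 54/0	bone	midden	Coromandel	D. novaezealandiae	D24	Wheritoa
AIM t12/26 n49/33	bone	midden	Coromandel	D. novaezealandiae	D23	Onemana
AIM AR3008	bone	midden	Coromandel	D. novaezealandiae	D24	Hot Water Beach
AIM AR3292	bone	midden	Coromandel	E. curtus	E14	Hot Water beach
AIM 2/c16 3/1 n40/6	bone	midden	Coromandel	E. curtus	E1	Opito
AIM AR5735	bone	midden	Taupo	D. novaezealandiae	D23	Whakamoenga Cave
AIM 2b18 3/1	bone	midden	Coromandel	D. novaezealandiae	D1	Opito
AIM B6143	femur	–	Mangaotaki	P. geranoides	P10	–
AIM B7021	femur	–	Waitanguru	D. novaezealandiae	D10	–
AIM B7101	femur	–	Doubtless Bay	D. novaezealandiae	D1	–
AU no lbl. bg G	bone	midden	Houhora	E. curtus	E14	–
AUG Av5801.7	femur	cave	Waitomo	A. didiformis	A1	24,800±450 yrBP*
AUG Av5801.8	femur	cave	Waitomo	A. didiformis	A1	24,800±450 yrBP*
AUG Av5801.9	femur	cave	Waitomo	E. curtus	E1	24,800±450 yrBP*
CM Av12567	femur	swamp	Te Aute	D. novaezealandiae	D25	–
CM Av13461	femur	–	Christchurch	D. robustus	Dr11	–
CM Av15891	femur	–	Kaikoura	D. robustus	Dr4	–
CM Av16361	femur	–	Castle Hill Basin	E. curtus	E9	–
CM Av19154	femur	–	Lake Coleridge	D. robustus	Dr16	–
CM Av19329	femur	swamp	Albury	D. robustus	Dr17	–
CM Av20607	femur	–	Doubtless Bay	E. curtus	E14	–
CM Av20621	femur	–	Benmore	D. robustus	Dr8	Loess ~10 kyrBP
CM Av20671	tarsometatarsus	midden	Te Rangatupu	D. novaezealandiae	D12	Site # N129/233
CM Av28271	femur	cave	Inangahua	D. robustus	Dr3	Limestone cave
CM Av28274	femur	cave	Inangahua	D. robustus	Dr10	Limestone cave
CM Av36160	femur	swamp	Hamilton's	D. robustus	Dr13	–
CM Av9033	femur	swamp	Te Aute	D. novaezealandiae	D3	–
CM unregistered	femur	reservoir	Cashmere	D. robustus	Dr2	~8-10 kyrBP
CM SB5	femur	–	Kakanui	D. robustus	Dr18
CM SB108	femur	–	Cheviot	D. robustus	Dr1	juvenile
MNZ S40870.2	phalanx	swamp	Tangatupura	P. geranoides	P6	18,300±160 yrBP*
OM Av3856	femur	–	Forest Hill	D. robustus	Dr7	–
OM Av3887	tibiotarsus	–	Karitane	D. robustus	Dr9	Central Otago
OM Av3935	femur	–	Ngapara	D. robustus	Dr2	–
OM Av3967	vertebrae	–	Glendhu Bay	D. robustus	Dr13	Central Otago
DM1	sternum	peat bog	Taihape	D. novaezealandiae	D27	–
DM2	femur	peat bog	Taihape	D. novaezealandiae	D27	–
DM3	pelvis	peat bog	Taihape	D. novaezealandiae	D27	–
DM4	tarsometatarsus	peat bog	Taihape	D. novaezealandiae	D5	–
DM5	tarsometatarsus	peat bog	Taihape	D. novaezealandiae	D27	–
DM6	femur	peat bog	Taihape	E. curtus	E14	–
DM7	tibiotarsus	peat bog	Taihape	D. novaezealandiae	D28	–
W 1617	femur	swamp	Makirikiri	E. curtus	E2	ID - T. H. Worthy
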
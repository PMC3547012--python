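sample_id	species	haplotype	sex
EW Av22	D. novaezealandiae	D3	F
EW Av23	D. novaezealandiae	D3	–
EW Av25	D. novaezealandiae	D17	F
EW Av26	D. novaezealandiae	D17	–
EW Av27	D. novaezealandiae	D17	F
EW Av28	D. novaezealandiae	D17	F
EW Av29	D. novaezealandiae	D3	M
EW Av30	A. didiformis	A2	–
EW Av32	E. curtus	E14	–
EW Av34	A. didiformis	A2	F
EW Av38	D. novaezealandiae	D17	–
EW Av100	D. novaezealandiae	D22	–
EW Av101	D. novaezealandiae	D6	–
EW Av103	D. novaezealandiae	D5	F
EW Av104	A. didiformis	A2	–
EW Av106	D. novaezealandiae	D21	F
EW Av107	D. novaezealandiae	D21	–
EW Av108	D. novaezealandiae	D6	–
EW Av200	D. novaezealandiae	D3	–
EW Av204	A. didiformis	A2	–
EW Av205	D. novaezealandiae	D3	F
EW Av206	A. didiformis	A2	F
EW Av207	A. didiformis	A2	F
EW Av332	D. novaezealandiae	D3	–
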
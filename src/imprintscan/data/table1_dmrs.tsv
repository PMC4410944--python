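kind	chrom	start	end	name	methylated_parent	cpgi	methylated	atrx	h3_3	daxx	h3k9me3	h4k20me3	h3k4me3	h3k27me3
germline	chr1	63246988	63247117	Zdbf2	maternal	no	yes	yes	mid	mid	high	low	mid	low
germline	chr2	174119625	174123318	Nespas-Gnasxl	maternal	yes	yes	yes	mid	high	high	high	low	high
germline	chr2	174152576	174154820	Gnas	maternal	yes	yes	no	mid	mid	mid	mid	low	high
germline	chr6	4695857	4699483	Peg10	maternal	yes	yes	mid	high	mid	high	high	mid	mid
germline	chr6	30684007	30689966	Peg1	maternal	yes	yes	yes	high	high	high	mid	mid	mid
germline	chr7	6680055	6685400	Peg3	maternal	yes	yes	yes	high	high	high	mid	low	mid
germline	chr7	67148447	67150182	Snrpn	maternal	no	yes	yes	high	mid	high	low	mid	low
germline	chr7	149765988	149768095	H19	paternal	no	yes	yes	mid	mid	high	mid	low	mid
germline	chr7	150479567	150482810	Lit1/Kcnq1ot1	maternal	yes	yes	mid	high	high	high	high	mid	mid
germline	chr9	89771586	89778464	Rasgrf1	paternal	no	yes	mid	high	mid	mid	low	low	high
germline	chr10	12809849	12811804	Zac1	maternal	yes	yes	yes	high	high	high	high	mid	high
germline	chr11	11925463	11927100	Meg1/Grb10	maternal	yes	yes	yes	high	mid	high	high	low	high
germline	chr11	22871974	22872993	Commd1	maternal	yes	yes	yes	high	high	mid	high	mid	low
germline	chr12	110765047	110769203	IG-DMR	paternal	yes	yes	yes	high	high	high	high	mid	mid
germline	chr15	96884878	96885292	Slc38a4	maternal	no	no	no	mid	mid	mid	mid	mid	mid
germline	chr17	12934169	12935733	Igf2r/Airn	maternal	yes	yes	yes	high	mid	high	mid	low	high
germline	chr18	13130435	13133135	Impact	maternal	yes	yes	yes	high	high	high	high	high	low
somatic	chr2	157385786	157386317	Nnat	maternal	yes	yes	yes	high	high	high	high	low	mid
somatic	chr6	58856717	58857141	Herc3	maternal	yes	yes	yes	high	high	high	high	low	mid
somatic	chr7	135831483	135832096	Inpp5f	maternal	yes	yes	yes	high	high	high	high	mid	mid
somatic	chr15	72639967	72640553	Trappc9	maternal	yes	yes	yes	high	high	high	high	low	mid
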
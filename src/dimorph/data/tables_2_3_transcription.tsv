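table	gene	ES	CP	8.5	9.5	10.5	p1	Adult	Chr
female	Hmgb3	XX							X
female	Dmrtb1	XX							4
female	Hoxb9	XX							11
female	Hoxc8	XX							15
female	Klf8	XX							X
female	Mitf	XX							6
female	Prdm14	XX							1
female	Rhox1	XX							X
female	Sohlh2	XX							3
female	Tbx15	XX							3
female	Zeb1	XX							18
female	Zfp182	XX							X
female	Zfp275	XX							X
female	Zfp449	XX							X
female	Zfp59	XX							7
female	Zxdb	XX							X
female	Mecp2	XX							X
female	Nkap	XX							X
female	Ogt	XX							X
female	Top2b	XX							14
female	Trim16	XX							11
female	Zmym3	XX							X
female	Apobec2	XX							17
female	Baz2b	XX							2
female	Prrx1	XX						XX	1
female	Kdm6a	XX					XX	XX	X
female	Lbh	XX						XX	17
female	Meis2	XX						XY	2
female	Zfp9	XX						XY	6
female	Aff2	XX	XX					nb	X
female	Atrx	XX			XY			nb	X
female	Arid1b	nb	XX		XX			nb	17
female	Bhlhe40	nb			XX			XX	6
female	Zfp51	nb	XX		XX				17
female	Klf15	nb			XX				6
female	Mafk	nb	XX		XX				5
female	Aff3	nb	XX			XX	XX	XY
female	Heyl							XX	4
female	Hopx							XX	5
female	Dlx1							XX	2
female	Rsl1							XX	13
female	Zbtb45							XX	7
female	Zfp282							XX	6
female	Zfp472							XX	17
female	Zfp498							XX	5
female	Zfp758							XX	17
female	Zkscan14							XX	5
female	Zkscan6							XX	11
female	Nat10							XX	2
female	Senp3							XX	11
female	Setmar							XX	6
female	Sirt7							XX	11
female	Suv39h2							XX	2
female	Bard1							XX	1
female	Cbx2							XX	11
female	Cbx7							XX	15
female	Rcc1							XX	4
female	Nkx2-5						XX	XX	17
female	Irf4							XX	13
female	Cecr2							XX	6
male	Egr4	XY							6
male	Cdx1	XY							18
male	E2f7	XY							10
male	Eomes	XY							9
male	Evx1	XY							6
male	Foxi3	XY							6
male	Foxp4	XY							17
male	Insm1	XY							2
male	Lin28a	XY							4
male	Mesp1	XY							7
male	Mixl1	XY							1
male	Nr6a1	XY							2
male	Pou2f3	XY							9
male	Sox11	XY							12
male	Sp5	XY							9
male	Sp8	XY							12
male	T	XY							17
male	Tcf7	XY							11
male	Wiz	XY							17
male	Ybx2	XY							11
male	Zglp1	XY							9
male	Dnmt3b	XY							2
male	Dnmt3l	XY							10
male	Phc1	XY							6
male	Plac8	XY							5
male	Tdrd5	XY							1
male	Bahcc1	XY							11
male	Kdm6c	XY	XY	XY	XY		XY	XY	Y
male	Bcl6b	XY	XY					nb	11
male	Irf8	XY	XY					nb	8
male	Arid1a	XY						XY	4
male	Lef1	XY		XY			XY	XY	3
male	Tbx20	XY	XY			XY	XY		9
male	Smarcd1	XY						XY	15
male	Zbtb7a	XY						XY	10
male	Hif3a	XY					XY	XY	7
male	Nfkb2	XY					XY	XY	19
male	Pbx2	XY	XY					nb	17
male	Prdm6	XY						XY	18
male	Id2	XY						XY	12
male	Dot1l	XY	XY					XX	10
male	Zfp296	XY						XX	7
male	Gata4	XY						nb	14
male	Mycn	XY						nb	12
male	Hdac5	XY						nb	11
male	Nfxl1	XY						nb	5
male	Pax6	nb	XY						2
male	Brd4	nb	XY					nb	17
male	Carhsp1	nb		XY	XY	XY			16
male	Csde1	nb	XY	XY			nb	nb	3
male	Mef2d	nb			XY				3
male	Atf5	nb						XY	7
male	Bach2	nb						XY	4
male	Cdc5l	nb						XY	17
male	Crebzf	nb						XY	7
male	Gm13139	nb						XY	4
male	Hmgb2	nb						XY	8
male	Klf10	nb						XY	15
male	Nfic	nb						XY	10
male	Nfkb1	nb						XY	3
male	Pias2	nb						XY	18
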
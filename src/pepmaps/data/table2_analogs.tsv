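set	peptide	v3_1	v3_2	v3_3	predicted_ic50_uM	ic50_uM	ic50_sd_uM	mode	hydrolyzed
1	IPI	0.725	0.059	0.725	238	3.9	1.0	competitive	no
1	AIP	-0.194	0.725	0.059	103
1	APA	-0.194	0.059	-0.194	988	44.3	3.2	competitive	no
1	APF	-0.194	0.059	0.716	168	65.8	5.5	competitive	no
1	APR	-0.194	0.059	-1.000	15	119.7	3.5	competitive	no
1	ARP	-0.194	-1.000	0.059	687
1	IFK	0.725	0.716	-0.991	34
1	IIF	0.725	0.725	0.716	71
1	IPA	0.725	0.059	-0.194	472	28.3	3.4	competitive	no
1	IRF	0.725	-1.000	0.716	476
1	IRK	0.725	-1.000	-0.991	107
1	KPA	-0.991	0.059	-0.194	22690	74.5	7.0	competitive	no
1	KRI	-0.991	-1.000	0.725	67699
1	RIF	-1.000	0.725	0.716	7435
1	RIR	-1.000	0.725	-1.000	662
1	RKR	-1.000	-0.991	-1.000	2451
2	FPF	0.716	0.059	0.716	177	247.0	32.7	competitive	yes
2	FPI	0.716	0.059	0.725	524	45.2	5.3	competitive	no
2	FPW	0.716	0.059	1.000	67	54.9	2.9	competitive	yes
2	IAI	0.725	-0.194	0.725	97
2	IPF	0.725	0.059	0.716	80	47.3	12.3	competitive	yes
2	IPW	0.725	0.059	1.000	31	175.3	5.5	competitive	yes
2	WPF	1.000	0.059	0.716	214	159.8	12.8	mixed	yes
2	WPI	1.000	0.059	0.725	633	133.0	14.7	mixed	no
2	WPW	1.000	0.059	1.000	81	120.1	13.1	mixed	yes
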
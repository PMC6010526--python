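peptide	ic50_uM
IPI	3.5
IPIQY	35.2
WL	43.6
LPVPQ	43.7
FLQP	65.3
IPM	79.4
LPVP	87.0
MPVQA	93.3
LPYPY	108.3
HL	143.2
IP	149.6
VA	168.2
LLQLEAIR	177.8
YPYY	194.4
LPQNIPPLT	205.2
VPGEIVE	224.5
LPL	241.4
YPY	243.7
LPLPL	325.0
LPLPLL	371.5
FL	399.6
IPSK	406.8
VLGP	580.4
RP	657.2
YP	658.1
LP	712.5
ILELA	721.1
AL	882.1
LW	993.4
QPLPPT	1013.8
SL	2517.1
GL	2615.0
EK	3216.8
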
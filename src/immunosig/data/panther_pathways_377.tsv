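# PANTHER pathway over/under-representation inputs for the 377-gene immune signature
# reference_size=20972	mapped_list_size=385
category_id	category	K	k
P00038	JAK/STAT signaling pathway	17	6
P00054	Toll receptor signaling pathway	60	21
P00036	Interleukin signaling pathway	98	23
P00053	T cell activation	96	22
P00010	B cell activation	72	15
P05918	p38 MAPK pathway	42	7
P00006	Apoptosis signaling pathway	122	20
P00031	Inflammation mediated by chemokine and cytokine signaling pathway	261	36
P00011	Blood coagulation	47	6
P00056	VEGF signaling pathway	72	8
P04393	Ras Pathway	76	8
P06959	CCKR signaling map	173	17
P00059	p53 pathway	88	8
P00005	Angiogenesis	176	16
P00034	Integrin signalling pathway	192	17
P00018	EGF receptor signaling pathway	139	11
P06664	Gonadotropin-releasing hormone receptor pathway	235	15
UNCLASSIFIED	Unclassified	18333	232
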
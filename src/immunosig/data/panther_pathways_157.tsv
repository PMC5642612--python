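# PANTHER pathway over/under-representation inputs for the 157-gene immune signature
# reference_size=20972	mapped_list_size=158
category_id	category	K	k
P00038	JAK/STAT signaling pathway	17	3
P00036	Interleukin signaling pathway	98	9
P00010	B cell activation	72	6
P00054	Toll receptor signaling pathway	60	5
P00053	T cell activation	96	7
P00031	Inflammation mediated by chemokine and cytokine signaling pathway	261	12
P00034	Integrin signalling pathway	192	8
UNCLASSIFIED	Unclassified	18333	96
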
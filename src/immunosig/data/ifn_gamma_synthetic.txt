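# Synthetic stand-in for a GSEA-style type-II interferon (IFN-gamma) pathway gene set (200 genes)
CCL1
CCL11
CCL13
CCL14
CCL15
CCL16
CCL17
CCL18
CCL19
CCL2
CCL20
CCL21
CCL22
CCL23
CCL24
CCL25
CCL26
CCL27
CCL28
CCL3
CXCL10
CXCL11
CXCL9
CXCR3
HLA-A
HLA-B
HLA-C
HLA-DMA
HLA-DMB
HLA-DOB
HLA-DPA1
HLA-DPB1
HLA-DQA1
HLA-DQB1
HLA-DRA
HLA-E
HLA-G
IFI16
IFI27
IFI35
IFIH1
IFIT1
IFIT2
IFITM1
IFITM2
IFNG
IFNGR1
IL10
IL10RA
IL11
IL11RA
IL12A
IL12B
IL12RB1
IL12RB2
IL13
IL13RA1
IL13RA2
IL15
IL15RA
IL16
IL17A
IL17B
IL17F
IL17RA
IL17RB
IL18
IL18R1
IL18RAP
IL19
IL1A
IL1B
IL1R1
IL1R2
IL1RAP
IL1RAPL2
IL1RL1
IL1RL2
IL1RN
IRF1
IRF2
IRF3
IRF4
IRF5
IRF7
IRF8
ISG15
ISG20
JAK1
JAK2
JAK3
SOCS1
STAT1
STAT2
STAT3
STAT4
STAT5B
STAT6
SYNIFNG001
SYNIFNG002
SYNIFNG003
SYNIFNG004
SYNIFNG005
SYNIFNG006
SYNIFNG007
SYNIFNG008
SYNIFNG009
SYNIFNG010
SYNIFNG011
SYNIFNG012
SYNIFNG013
SYNIFNG014
SYNIFNG015
SYNIFNG016
SYNIFNG017
SYNIFNG018
SYNIFNG019
SYNIFNG020
SYNIFNG021
SYNIFNG022
SYNIFNG023
SYNIFNG024
SYNIFNG025
SYNIFNG026
SYNIFNG027
SYNIFNG028
SYNIFNG029
SYNIFNG030
SYNIFNG031
SYNIFNG032
SYNIFNG033
SYNIFNG034
SYNIFNG035
SYNIFNG036
SYNIFNG037
SYNIFNG038
SYNIFNG039
SYNIFNG040
SYNIFNG041
SYNIFNG042
SYNIFNG043
SYNIFNG044
SYNIFNG045
SYNIFNG046
SYNIFNG047
SYNIFNG048
SYNIFNG049
SYNIFNG050
SYNIFNG051
SYNIFNG052
SYNIFNG053
SYNIFNG054
SYNIFNG055
SYNIFNG056
SYNIFNG057
SYNIFNG058
SYNIFNG059
SYNIFNG060
SYNIFNG061
SYNIFNG062
SYNIFNG063
SYNIFNG064
SYNIFNG065
SYNIFNG066
SYNIFNG067
SYNIFNG068
SYNIFNG069
SYNIFNG070
SYNIFNG071
SYNIFNG072
SYNIFNG073
SYNIFNG074
SYNIFNG075
SYNIFNG076
SYNIFNG077
SYNIFNG078
SYNIFNG079
SYNIFNG080
SYNIFNG081
SYNIFNG082
SYNIFNG083
SYNIFNG084
SYNIFNG085
SYNIFNG086
SYNIFNG087
SYNIFNG088
SYNIFNG089
SYNIFNG090
SYNIFNG091
SYNIFNG092
SYNIFNG093
SYNIFNG094
SYNIFNG095
SYNIFNG096
SYNIFNG097
SYNIFNG098
SYNIFNG099
TAP1
TAP2
TAPBP
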
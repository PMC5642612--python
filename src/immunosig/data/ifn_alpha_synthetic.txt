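# Synthetic stand-in for a GSEA-style type-I interferon (IFN-alpha) pathway gene set (97 genes)
A2M
ABCB1
ABL1
ADA
ADORA2A
AICDA
AIRE
AKT3
ALCAM
AMBP
AMICA1
ANP32B
ANXA1
APOE
APP
ARG1
ARG2
ATF1
ATF2
ATG10
ATG12
ATG16L1
ATG5
ATG7
ATM
AXL
BAGE
DDX58
IFI16
IFI27
IFI35
IFIH1
IFIT1
IFIT2
IFITM1
IFITM2
IFNA1
IFNA17
IFNA2
IFNA7
IFNA8
IFNAR1
IFNAR2
IRF3
IRF7
ISG15
ISG20
MX1
OAS3
SYNIFNA001
SYNIFNA002
SYNIFNA003
SYNIFNA004
SYNIFNA005
SYNIFNA006
SYNIFNA007
SYNIFNA008
SYNIFNA009
SYNIFNA010
SYNIFNA011
SYNIFNA012
SYNIFNA013
SYNIFNA014
SYNIFNA015
SYNIFNA016
SYNIFNA017
SYNIFNA018
SYNIFNA019
SYNIFNA020
SYNIFNA021
SYNIFNA022
SYNIFNA023
SYNIFNA024
SYNIFNA025
SYNIFNA026
SYNIFNA027
SYNIFNA028
SYNIFNA029
SYNIFNA030
SYNIFNA031
SYNIFNA032
SYNIFNA033
SYNIFNA034
SYNIFNA035
SYNIFNA036
SYNIFNA037
SYNIFNA038
SYNIFNA039
SYNIFNA040
SYNIFNA041
SYNIFNA042
SYNIFNA043
SYNIFNA044
SYNIFNA045
SYNIFNA046
SYNIFNA047
SYNIFNA048
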
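# Synthetic stand-in for a T-cell cytotoxicity pathway gene set (115 genes)
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
CD247
CD33
CD34
CD36
CD37
CD38
CD3D
CD3E
CD3EAP
CD3G
CD80
CD81
CD83
CD84
CD86
CD8A
CD8B
CTSW
EOMES
FAS
GNLY
GZMA
GZMB
GZMH
GZMK
GZMM
KIR2DL1
KIR2DL3
KIR3DL1
KIR3DL2
KIR3DL3
KLRB1
KLRC1
KLRC2
KLRD1
KLRF1
KLRG1
KLRK1
NCR1
PRF1
SYNCYTO001
SYNCYTO002
SYNCYTO003
SYNCYTO004
SYNCYTO005
SYNCYTO006
SYNCYTO007
SYNCYTO008
SYNCYTO009
SYNCYTO010
SYNCYTO011
SYNCYTO012
SYNCYTO013
SYNCYTO014
SYNCYTO015
SYNCYTO016
SYNCYTO017
SYNCYTO018
SYNCYTO019
SYNCYTO020
SYNCYTO021
SYNCYTO022
SYNCYTO023
SYNCYTO024
SYNCYTO025
SYNCYTO026
SYNCYTO027
SYNCYTO028
SYNCYTO029
SYNCYTO030
SYNCYTO031
SYNCYTO032
SYNCYTO033
SYNCYTO034
SYNCYTO035
SYNCYTO036
SYNCYTO037
SYNCYTO038
SYNCYTO039
SYNCYTO040
SYNCYTO041
SYNCYTO042
SYNCYTO043
SYNCYTO044
SYNCYTO045
SYNCYTO046
SYNCYTO047
SYNCYTO048
SYNCYTO049
SYNCYTO050
SYNCYTO051
SYNCYTO052
SYNCYTO053
SYNCYTO054
SYNCYTO055
TBX21
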
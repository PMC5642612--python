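# nCounter PanCancer-style immune profiling panel (722 genes)
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
BATF
BAX
BCL10
BCL2
BCL2L1
BCL6
BID
BIRC5
BLK
BLNK
BMI1
BST1
BST2
BTK
BTLA
C1QA
C1QB
C1QBP
C1R
C1S
C2
C3
C3AR1
C4BPA
C5
C6
C7
C8A
C8B
C8G
C9
CAMP
CARD11
CARD9
CASP1
CASP10
CASP3
CASP8
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
CCL3L1
CCL4
CCL5
CCL7
CCL8
CCND3
CCR1
CCR2
CCR3
CCR4
CCR5
CCR6
CCR7
CCR9
CCRL2
CD14
CD160
CD163
CD164
CD180
CD19
CD1A
CD1B
CD1C
CD1D
CD1E
CD2
CD200
CD207
CD209
CD22
CD24
CD244
CD247
CD27
CD274
CD276
CD28
CD33
CD34
CD36
CD37
CD38
CD3D
CD3E
CD3EAP
CD3G
CD4
CD40
CD40LG
CD44
CD46
CD47
CD48
CD5
CD53
CD55
CD58
CD59
CD6
CD63
CD68
CD7
CD70
CD74
CD79A
CD79B
CD80
CD81
CD83
CD84
CD86
CD8A
CD8B
CD9
CD96
CD97
CD99
CDH1
CDH5
CDK1
CDKN1A
CEACAM1
CEACAM6
CEACAM8
CEBPB
CFB
CFD
CFI
CFP
CHIT1
CHUK
CKLF
CLEC4A
CLEC4C
CLEC5A
CLEC6A
CLEC7A
CLU
CMA1
CMKLR1
COL3A1
COLEC12
CR1
CR2
CREB1
CREB5
CREBBP
CRP
CSF1
CSF1R
CSF2
CSF2RB
CSF3
CSF3R
CT45A1
CTAG1B
CTAGE1
CTCFL
CTLA4
CTSG
CTSH
CTSL1
CTSS
CTSW
CX3CL1
CX3CR1
CXCL1
CXCL10
CXCL11
CXCL12
CXCL13
CXCL14
CXCL16
CXCL2
CXCL3
CXCL5
CXCL6
CXCL9
CXCR1
CXCR2
CXCR3
CXCR4
CXCR5
CXCR6
CYBB
CYFIP2
CYLD
DDX43
DDX58
DEFB1
DMBT1
DOCK9
DPP4
DUSP4
DUSP6
EBI3
ECSIT
EGR1
EGR2
ELANE
ELK1
ENG
ENTPD1
EOMES
EP300
EPCAM
ETS1
EWSR1
F12
F13A1
F2RL1
FADD
FAS
FCER1A
FCER1G
FCER2
FCGR1A
FCGR2A
FCGR2B
FCGR3A
FEZ1
FLT3
FLT3LG
FN1
FOS
FOXJ1
FOXP3
FPR2
FUT5
FUT7
FYN
GAGE1
GATA3
GNLY
GPI
GPR44
GTF3C1
GZMA
GZMB
GZMH
GZMK
GZMM
HAMP
HAVCR2
HCK
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
HMGB1
HRAS
HSD11B1
ICAM1
ICAM2
ICAM3
ICAM4
ICOS
ICOSLG
IDO1
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
IFNB1
IFNG
IFNGR1
IGF1R
IGF2R
IGLL1
IKBKB
IKBKE
IKBKG
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
IL2
IL21
IL21R
IL22
IL22RA1
IL22RA2
IL23A
IL23R
IL24
IL25
IL26
IL27
IL28A
IL29
IL2RA
IL2RB
IL2RG
IL3
IL32
IL34
IL3RA
IL4
IL4R
IL5
IL5RA
IL6
IL6R
IL6ST
IL7
IL7R
IL9
ILF3
INPP5D
IRAK1
IRAK2
IRAK4
IRF1
IRF2
IRF3
IRF4
IRF5
IRF7
IRF8
IRGM
ISG15
ISG20
ITCH
ITGA1
ITGA2
ITGA2B
ITGA4
ITGA5
ITGA6
ITGAE
ITGAL
ITGAM
ITGAX
ITGB1
ITGB2
ITGB3
ITGB4
ITK
JAK1
JAK2
JAK3
JAM3
KIR2DL1
KIR2DL3
KIR3DL1
KIR3DL2
KIR3DL3
KIT
KLRB1
KLRC1
KLRC2
KLRD1
KLRF1
KLRG1
KLRK1
LAG3
LAIR2
LAMP1
LAMP2
LAMP3
LBP
LCK
LCN2
LCP1
LGALS3
LIF
LILRA1
LILRA4
LILRA5
LILRB1
LILRB2
LILRB3
LRP1
LRRN3
LTA
LTB
LTBR
LTF
LTK
LY86
LY9
LY96
LYN
MAF
MAGEA1
MAGEA12
MAGEA3
MAGEA4
MAGEB2
MAGEC1
MAGEC2
MAP2K1
MAP2K2
MAP2K4
MAP3K1
MAP3K5
MAP3K7
MAP4K2
MAPK1
MAPK11
MAPK14
MAPK3
MAPK8
MAPKAPK2
MARCO
MASP1
MASP2
MAVS
MBL2
MCAM
MEF2C
MEFV
MERTK
MFGE8
MICA
MICB
MIF
MME
MNX1
MPPED1
MR1
MRC1
MS4A1
MS4A2
MSR1
MST1R
MUC1
MX1
MYD88
NCAM1
NCF4
NCR1
NEFL
NFATC1
NFATC2
NFATC3
NFATC4
NFKB1
NFKB2
NFKBIA
NLRC5
NLRP3
NOD1
NOD2
NOTCH1
NRP1
NT5E
NUP107
OAS3
OSM
PASD1
PAX5
PBK
PDCD1
PDCD1LG2
PDGFC
PDGFRB
PECAM1
PIK3CD
PIK3CG
PIN1
PLA2G1B
PLA2G6
PLAU
PLAUR
PMCH
PNMA1
POU2AF1
POU2F2
PPARG
PPBP
PRAME
PRF1
PRG2
PRKCD
PRKCE
PRM1
PSEN1
PSEN2
PSMB10
PSMB7
PSMB8
PSMB9
PSMD7
PTGS2
PTPRC
PVR
PYCARD
RAG1
REL
RELA
RELB
REPS1
RIPK2
ROPN1
RORA
RORC
RPS6
RRAD
RUNX1
RUNX3
S100A12
S100A7
S100A8
S100B
SAA1
SBNO2
SELE
SELL
SELPLG
SEMG1
SERPINB2
SERPING1
SH2B2
SH2D1A
SH2D1B
SIGIRR
SIGLEC1
SLAMF1
SLAMF6
SLAMF7
SLC11A1
SMAD2
SMAD3
SMPD3
SOCS1
SPA17
SPACA3
SPINK5
SPN
SPO11
SPP1
SSX1
SSX4
ST6GAL1
STAT1
STAT2
STAT3
STAT4
STAT5B
STAT6
SYCP1
SYK
SYT17
TAB1
TAL1
TANK
TAP1
TAP2
TAPBP
TARP
TBK1
TBX21
TCF7
TFE3
TFEB
TFRC
TGFB1
TGFB2
THBD
THBS1
THY1
TICAM1
TICAM2
TIGIT
TIRAP
TLR1
TLR10
TLR2
TLR3
TLR4
TLR5
TLR6
TLR7
TLR8
TLR9
TMEFF2
TNF
TNFAIP3
TNFRSF10B
TNFRSF10C
TNFRSF11A
TNFRSF11B
TNFRSF12A
TNFRSF13B
TNFRSF13C
TNFRSF14
TNFRSF17
TNFRSF18
TNFRSF1A
TNFRSF1B
TNFRSF4
TNFRSF8
TNFRSF9
TNFSF10
TNFSF11
TNFSF12
TNFSF13
TNFSF13B
TNFSF14
TNFSF15
TNFSF18
TNFSF4
TNFSF8
TOLLIP
TP53
TPSAB1
TPTE
TRAF2
TRAF3
TRAF6
TREM1
TREM2
TTK
TXK
TXNIP
TYK2
UBC
ULBP2
USP9Y
VCAM1
VEGFA
VEGFC
XCL2
XCR1
YTHDF2
ZAP70
ZNF205
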
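gene_id	systematic_id	go_slim	sites	phosphogrid_positions	phenotypes	interaction	sdl_score	rescue	invitro	manual_include	known_substrate
GPD1	YDL022W	Known Ypk1 Substrates	24	24		1	+++	N/A	+	1	1
FPK1	YNR047W	Known Ypk1 Substrates	37,200,244,436,481			1	+	N/A	+	0	1
FPK1(D621A)	YNR047W	Known Ypk1 Substrates	37,200,244,436,481			1	++	N/A	+	0	1
ORM1	YGR038W	Known Ypk1 Substrates	52,53			1	+++	N/A	+	0	1
ORM2	YLR350W	Known Ypk1 Substrates	47,48			1	++++	N/A	+	0	1
AVO1	YOL078W	Cytoskeleton Organization	552,597,1078	552		1	-	N/A	N/A	0	0
AVO2	YMR068W	Cytoskeleton Organization	273,305,407	273		1	-	N/A	N/A	0	0
BEM2	YER155C	Cytoskeleton Organization	83,168,1810,1813		Myr	1	-	N/A	N/A	0	0
BNI1	YNL271C	Cytoskeleton Organization	119,1138,1533	1138	AbA,Casp	1	-	N/A	N/A	0	0
CDH1	YGL003C	Cytoskeleton Organization	51,195,213	213	AbA	1	TOXIC	-	N/A	0	0
ENT1	YDL161W	Cytoskeleton Organization	160	160		1	-	N/A	N/A	0	0
GIC2	YDR309C	Cytoskeleton Organization	90,312,345	345	Myr,AbA	0	-	N/A	N/A	0	0
LSB3	YFR024C-A	Cytoskeleton Organization	262	262		1	-	N/A	N/A	0	0
PAL1	YDR348C	Cytoskeleton Organization	49,391,436	49	AbA,Casp	0	++++	N/A	-	0	0
SLA1	YBL007C	Cytoskeleton Organization	445,447,449,477	447,449		1	-	N/A	N/A	0	0
TSC11	YER093C	Cytoskeleton Organization	19,97,188	19		1	N/A	N/A	N/A	0	0
YHR097C	YHR097C	Cytoskeleton Organization	58,288,294	288,294	Myr	0	+++	N/A	+/-	0	0
YSC84	YHR016C	Cytoskeleton Organization	274,374	374	Myr	1	-	N/A	N/A	0	0
COM2	YER130C	Biological Process Unknown	251,370,380		Myr	1	-	N/A	N/A	0	0
ECM3	YOR092W	Biological Process Unknown	312,350		Myr,AbA	1	-	N/A	N/A	1	0
ICS2	YBR157C	Biological Process Unknown	14,95,136,172	172	Myr	0	-	N/A	N/A	0	0
JIP4	YDR475C	Biological Process Unknown	348,352,592,649		Myr,AbA	0	N/A	N/A	N/A	0	0
KKQ8	YKL168C	Biological Process Unknown	83,113,144,146,212,293			1	-	N/A	N/A	0	0
RTS3	YGR161C	Biological Process Unknown	30,238	238		1	-	N/A	N/A	1	0
SEG1	YMR086W	Biological Process Unknown	56,118,217,634,752	118,752	Myr	0	+	N/A	N/A	0	0
YDR186C	YDR186C	Biological Process Unknown	334,540,542,620,715	334,540,542,715		1	-	N/A	N/A	0	0
YHR080C	YHR080C	Biological Process Unknown	401,513,667			1	-	N/A	N/A	0	0
YNR014W	YNR014W	Biological Process Unknown	54,115,156,197			1	+++	N/A	+	0	0
YPK3	YBR028C	Biological Process Unknown	72,73,90	90	Myr,Casp	0	-	N/A	N/A	0	0
EPL1	YFL024C	Transcription from RNA Polymerase II Promoter	24,28,61			1	-	N/A	N/A	0	0
FKH1	YIL131C	Transcription from RNA Polymerase II Promoter	404		Myr	1	TOXIC	-	-	0	0
GAL11	YOL051W	Transcription from RNA Polymerase II Promoter	1003	1003	Myr	1	-	N/A	N/A	0	0
HCM1	YCR065W	Transcription from RNA Polymerase II Promoter	80		AbA	1	-	N/A	N/A	1	0
HOT1	YMR172W	Transcription from RNA Polymerase II Promoter	387,520,586		Myr	0	-	N/A	N/A	1	0
RLM1	YPL089C	Transcription from RNA Polymerase II Promoter	20		Myr	0	TOXIC	-	N/A	1	0
SMP1	YBR182C	Transcription from RNA Polymerase II Promoter	20,107			1	TOXIC	+	+	1	0
SSN2	YDR443C	Transcription from RNA Polymerase II Promoter	608	608	Myr	0	-	N/A	N/A	0	0
YHP1	YDR451C	Transcription from RNA Polymerase II Promoter	180,182		Myr	0	-	N/A	N/A	1	0
BCK2	YER167W	Mitotic Cell Cycle	12,38,373,430			1	TOXIC	-	N/A	0	0
ESC2	YDR363W	Mitotic Cell Cycle	114,143,145			1	-	N/A	N/A	0	0
PTK2	YJR059W	Mitotic Cell Cycle	59,82,91,171,275	59	Myr	1	+	N/A	N/A	0	0
SET3	YKR029C	Mitotic Cell Cycle	236,405,428			1	-	N/A	N/A	0	0
SWI4	YER111C	Mitotic Cell Cycle	816	816	Myr	1	-	N/A	N/A	0	0
VHS2	YIL135C	Mitotic Cell Cycle	316,318,325	325	Myr,Casp	0	-	N/A	N/A	0	0
ZDS1	YMR273C	Mitotic Cell Cycle	78,370		AbA	1	-	N/A	N/A	1	0
ZDS2	YML109W	Mitotic Cell Cycle	183,267,345			1	-	N/A	N/A	0	0
HAL5	YJL165C	Protein Phosphorylation	17,217,233	17,217		1	-	N/A	N/A	0	0
KIN1	YDR122W	Protein Phosphorylation	652,791,879,986	791,986		1	+	N/A	N/A	0	0
KIN2	YLR096W	Protein Phosphorylation	665,818,1020	665	Myr	0	-	N/A	N/A	0	0
KSP1	YHR082C	Protein Phosphorylation	594,827,884	827,884	Myr,AbA	1	TOXIC	-	N/A	0	0
NPR1	YNL183C	Protein Phosphorylation	125,255,257,317	125,255,257,317		1	++++	N/A	-	0	0
SKY1	YMR216C	Protein Phosphorylation	383	383	Myr	1	-	N/A	N/A	0	0
YAK1	YJL141C	Protein Phosphorylation	128,206,240	128	Myr,Casp	1	-	N/A	N/A	0	0
YPL150W	YPL150W	Protein Phosphorylation	371,452,890	371		1	-	N/A	N/A	0	0
ADR1	YDR216W	Lipid Metabolic Process	180,230,756	230	Myr,AbA	0	-	N/A	N/A	0	0
CDC1	YDR182W	Lipid Metabolic Process	9			0	-	N/A	+	1	0
CKI1	YLR133W	Lipid Metabolic Process	14,25,30	14,25,30	Myr,AbA	1	-	N/A	N/A	0	0
GPT2	YKR067W	Lipid Metabolic Process	27,652		Myr	0	+++	N/A	+	0	0
LAC1	YKL008C	Lipid Metabolic Process	23,24		Myr	1	+++	N/A	+	1	0
LAG1	YHL003C	Lipid Metabolic Process	24	24	Myr	1	+++	N/A	+	0	0
LCB3	YJL134W	Lipid Metabolic Process	16	16	Myr	1	-	N/A	+	0	0
AVT3	YKL146W	Cellular Ion Homeostasis and Transport	55,59,172,174	59	Myr,AbA	1	-	N/A	N/A	0	0
CCH1	YGR217W	Cellular Ion Homeostasis and Transport	146,148,347			1	-	N/A	+	0	0
FPS1	YLL043W	Cellular Ion Homeostasis and Transport	147,181,185,570	570	Myr	1	+++++	N/A	+	0	0
MNR2	YKL064W	Cellular Ion Homeostasis and Transport	165,620,621,826		AbA	0	-	N/A	N/A	0	0
NHA1	YLR138W	Cellular Ion Homeostasis and Transport	544,830		Myr	1	-	N/A	N/A	1	0
PPZ1	YML016C	Cellular Ion Homeostasis and Transport	122,203,250	250	Myr	1	TOXIC	-	N/A	0	0
DED1	YOR204W	Translation	84,576	576		1	-	N/A	N/A	0	0
HCR1	YLR192C	Translation	223		Myr,AbA	1	-	N/A	N/A	1	0
HEF3	YNL014W	Translation	898		Myr,AbA	1	-	N/A	N/A	1	0
RPL3	YOR063W	Translation	24,337	24	Myr,AbA	1	-	N/A	N/A	0	0
SUI2	YJR007W	Translation	58		Myr	0	-	N/A	N/A	1	0
TEF1	YPR080W	Translation	72	72	Myr	0	-	N/A	N/A	1	0
BPH1	YCR032W	Cell Wall Organization or Biogenesis	1334,1336,1963		Casp	0	-	N/A	N/A	0	0
CSR2	YPR030W	Cell Wall Organization or Biogenesis	61,103,525,987		Myr	0	-	N/A	N/A	0	0
ROM2	YLR371W	Cell Wall Organization or Biogenesis	76,193,396	76,193		1	-	N/A	N/A	0	0
SSD1	YDR293C	Cell Wall Organization or Biogenesis	164,482,503	164,482	Myr,AbA	1	TOXIC	-	N/A	0	0
BRE5	YNR051C	Golgi Vesicle Transport	398	398	Myr	1	+++	N/A	-	0	0
EXO84	YBR102C	Golgi Vesicle Transport	76,313,494,554			1	-	N/A	N/A	0	0
MUK1	YPL070W	Golgi Vesicle Transport	173,184,185	184,185	Myr	0	+++	N/A	+/-	0	0
RGP1	YDR137W	Golgi Vesicle Transport	220,364,450,452	364		1	-	N/A	N/A	0	0
IRA2	YOL081W	Signaling	882,884,1578,1745,3069			1	N/A	N/A	N/A	0	0
GIS3	YLR094C	Signaling	249,333		Myr,AbA	0	-	N/A	N/A	1	0
MDS3	YGL197W	Signaling	757,824,842,851,1204		Myr,AbA	1	+++	N/A	-	0	0
SYT1	YPR095C	Signaling	277,410,728	277		1	N/A	N/A	N/A	0	0
CDC13	YDL220C	DNA Replication	314,333	333		1	TOXIC	-	N/A	0	0
CTI6	YPL181W	DNA Replication	155,216	216	Myr	1	-	N/A	N/A	0	0
RIM4	YHL024W	DNA Replication	93,429,525,607			1	-	N/A	N/A	0	0
ALY2	YJL084C	Endocytosis	166,201,225,803	166	Myr	0	-	N/A	N/A	0	0
ROD1	YOR018W	Endocytosis	563,617,807,823		Myr	0	+++	N/A	+/-	0	0
ROG3	YFR022W	Endocytosis	425,584,718			1	-	N/A	N/A	0	0
FRT1	YOR324C	Other	167,201,203,228,385	228	Myr	1	-	N/A	N/A	0	0
HER1	YOR227W	Other	28,102,157	28,102,157	Myr,AbA	0	TOXIC	-	+	0	0
YSP2	YDR326C	Other	326,518,1237		Myr	1	+++	N/A	+	0	0
JSN1	YJR091C	RNA Catabolic Process	174,275,600	275		1	-	N/A	N/A	0	0
PUF2	YPR042C	RNA Catabolic Process	55,143,246,902		Myr	0	N/A	N/A	N/A	0	0
CYK3	YDL117W	Cytokinesis	159,207,746	207	AbA	1	+++	N/A	-	0	0
DSN1	YIR010W	Chromosome Segregation	240,250	250		1	-	N/A	N/A	0	0
PEX31	YGR004W	Peroxisome Organization	432	432		1	++	N/A	+	0	0
PAM1	YDR251W	Pseudohyphal Growth	471,553,625	553	Myr,AbA,Casp	1	-	N/A	N/A	0	0
ATG21	YPL100W	Response to Starvation	191,237	237	Myr	0	+++	N/A	+	0	0
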
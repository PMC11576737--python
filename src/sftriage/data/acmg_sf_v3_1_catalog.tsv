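symbol	inheritance	category	phenotype	sf_version	lof_gene
APC	AD	cancer	Familial adenomatous polyposis	v3.1	1
RET	AD	cancer	Familial medullary thyroid cancer	v3.1	0
BRCA1	AD	cancer	Hereditary breast and/or ovarian cancer	v3.1	1
BRCA2	AD	cancer	Hereditary breast and/or ovarian cancer	v3.1	1
PALB2	AD	cancer	Hereditary breast and/or ovarian cancer	v3.1	1
SDHD	AD	cancer	Hereditary paraganglioma-pheochromocytoma syndrome	v3.1	1
SDHAF2	AD	cancer	Hereditary paraganglioma-pheochromocytoma syndrome	v3.1	1
SDHC	AD	cancer	Hereditary paraganglioma-pheochromocytoma syndrome	v3.1	1
SDHB	AD	cancer	Hereditary paraganglioma-pheochromocytoma syndrome	v3.1	1
MAX	AD	cancer	Hereditary paraganglioma-pheochromocytoma syndrome	v3.1	1
TMEM127	AD	cancer	Hereditary paraganglioma-pheochromocytoma syndrome	v3.1	1
BMPR1A	AD	cancer	Juvenile polyposis syndrome	v3.1	1
SMAD4	AD	cancer	Juvenile polyposis syndrome	v3.1	1
TP53	AD	cancer	Li-Fraumeni syndrome	v3.1	1
MLH1	AD	cancer	Lynch syndrome	v3.1	1
MSH2	AD	cancer	Lynch syndrome	v3.1	1
MSH6	AD	cancer	Lynch syndrome	v3.1	1
PMS2	AD	cancer	Lynch syndrome	v3.1	1
MEN1	AD	cancer	Multiple endocrine neoplasia type 1	v3.1	1
MUTYH	AR	cancer	MUTYH-associated polyposis	v3.1	1
NF2	AD	cancer	Neurofibromatosis type 2	v3.1	1
STK11	AD	cancer	Peutz-Jeghers syndrome	v3.1	1
PTEN	AD	cancer	PTEN hamartoma tumor syndrome	v3.1	1
RB1	AD	cancer	Retinoblastoma	v3.1	1
TSC1	AD	cancer	Tuberous sclerosis complex	v3.1	1
TSC2	AD	cancer	Tuberous sclerosis complex	v3.1	1
VHL	AD	cancer	von Hippel-Lindau syndrome	v3.1	1
WT1	AD	cancer	WT1-related Wilms tumor	v3.1	1
FBN1	AD	cardiovascular	Marfan syndrome	v3.1	1
TGFBR1	AD	cardiovascular	Loeys-Dietz syndrome	v3.1	0
TGFBR2	AD	cardiovascular	Loeys-Dietz syndrome	v3.1	0
SMAD3	AD	cardiovascular	Loeys-Dietz syndrome	v3.1	1
ACTA2	AD	cardiovascular	Familial thoracic aortic aneurysm and dissection	v3.1	0
MYH11	AD	cardiovascular	Familial thoracic aortic aneurysm and dissection	v3.1	0
PKP2	AD	cardiovascular	Arrhythmogenic right ventricular cardiomyopathy	v3.1	1
DSP	AD	cardiovascular	Arrhythmogenic right ventricular cardiomyopathy	v3.1	1
DSC2	AD	cardiovascular	Arrhythmogenic right ventricular cardiomyopathy	v3.1	1
DSG2	AD	cardiovascular	Arrhythmogenic right ventricular cardiomyopathy	v3.1	1
TMEM43	AD	cardiovascular	Arrhythmogenic right ventricular cardiomyopathy	v3.1	0
RYR2	AD	cardiovascular	Catecholaminergic polymorphic ventricular tachycardia	v3.1	0
CASQ2	AR	cardiovascular	Catecholaminergic polymorphic ventricular tachycardia	v3.1	1
TRDN	AR	cardiovascular	Catecholaminergic polymorphic ventricular tachycardia	v3.1	1
CALM1	AD	cardiovascular	Catecholaminergic polymorphic ventricular tachycardia / long QT syndrome	v3.1	0
CALM2	AD	cardiovascular	Catecholaminergic polymorphic ventricular tachycardia / long QT syndrome	v3.1	0
CALM3	AD	cardiovascular	Catecholaminergic polymorphic ventricular tachycardia / long QT syndrome	v3.1	0
TNNT2	AD	cardiovascular	Dilated cardiomyopathy	v3.1	0
LMNA	AD	cardiovascular	Dilated cardiomyopathy	v3.1	1
FLNC	AD	cardiovascular	Dilated cardiomyopathy	v3.1	1
TTN	AD	cardiovascular	Dilated cardiomyopathy	v3.1	1
BAG3	AD	cardiovascular	Dilated cardiomyopathy	v3.1	1
DES	AD	cardiovascular	Dilated cardiomyopathy	v3.1	0
RBM20	AD	cardiovascular	Dilated cardiomyopathy	v3.1	0
TNNC1	AD	cardiovascular	Dilated cardiomyopathy	v3.1	0
COL3A1	AD	cardiovascular	Ehlers-Danlos syndrome, vascular type	v3.1	1
LDLR	SD	cardiovascular	Familial hypercholesterolemia	v3.1	1
APOB	AD	cardiovascular	Familial hypercholesterolemia	v3.1	0
PCSK9	AD	cardiovascular	Familial hypercholesterolemia	v3.1	0
MYH7	AD	cardiovascular	Hypertrophic cardiomyopathy	v3.1	0
MYBPC3	AD	cardiovascular	Hypertrophic cardiomyopathy	v3.1	1
TNNI3	AD	cardiovascular	Hypertrophic cardiomyopathy	v3.1	0
TPM1	AD	cardiovascular	Hypertrophic cardiomyopathy	v3.1	0
MYL3	AD	cardiovascular	Hypertrophic cardiomyopathy	v3.1	0
ACTC1	AD	cardiovascular	Hypertrophic cardiomyopathy	v3.1	0
PRKAG2	AD	cardiovascular	Hypertrophic cardiomyopathy	v3.1	0
MYL2	AD	cardiovascular	Hypertrophic cardiomyopathy	v3.1	0
KCNQ1	AD	cardiovascular	Long QT syndrome types 1 and 2	v3.1	1
KCNH2	AD	cardiovascular	Long QT syndrome types 1 and 2	v3.1	1
SCN5A	AD	cardiovascular	Long QT syndrome 3, Brugada syndrome	v3.1	1
HNF1A	AD	miscellaneous	Maturity-onset diabetes of the young	v3.1	1
RYR1	AD	miscellaneous	Malignant hyperthermia	v3.1	0
CACNA1S	AD	miscellaneous	Malignant hyperthermia	v3.1	0
TTR	AD	miscellaneous	Hereditary TTR amyloidosis	v3.1	0
OTC	XL	miscellaneous	Ornithine transcarbamylase deficiency	v3.1	1
GLA	XL	miscellaneous	Fabry disease	v3.1	1
ATP7B	AR	miscellaneous	Wilson disease	v3.1	1
BTD	AR	miscellaneous	Biotinidase deficiency	v3.1	1
GAA	AR	miscellaneous	Pompe disease	v3.1	1
RPE65	AR	miscellaneous	RPE65-related retinopathy	v3.1	1
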
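symbol,alias,ncbi_gene_id,mr_kd,unique_peptides,percent_coverage,log_e,group,ptm_tag
PBRM1,BAF180,55193,181,27,24,-307.4,Chromatin Remodelling Factors,
SMARCC2,BAF170,6601,132.8,23,36,-263.5,Chromatin Remodelling Factors,
SMARCA4,BRG1,6597,188,21,23,-224.6,Chromatin Remodelling Factors,
SMARCD1,BAF60A,6602,58.2,11,34,-135.3,Chromatin Remodelling Factors,
BRD7,BRD7,29117,74.1,10,21,-97.3,Chromatin Remodelling Factors,
SMARCC1,BAF155,6599,122.8,10,20,-183.8,Chromatin Remodelling Factors,
CHD4,CHD4,1108,217.9,9,8,-81,Chromatin Remodelling Factors,
ACTL6A,BAF53A,86,43.2,8,40,-76.9,Chromatin Remodelling Factors,
SMARCE1,BAF57,6605,46.6,8,32,-101.9,Chromatin Remodelling Factors,
SMARCA1,SNF2L,6594,121.1,6,8,-45.8,Chromatin Remodelling Factors,
SMARCD2,BAF60B,6603,58.9,6,23,-54.6,Chromatin Remodelling Factors,
SMARCA2,Brm,6595,181.2,5,7,-128.4,Chromatin Remodelling Factors,
SMARCB1,BAF47,6598,44.1,4,14,-42.2,Chromatin Remodelling Factors,
ARID1A,BAF250,8289,218.2,3,4,-18.2,Chromatin Remodelling Factors,
CHD7,KAL5,55636,335.7,2,1,-11.1,Chromatin Remodelling Factors,
BPTF,NURF301,2186,324.9,2,1,-10.7,Chromatin Remodelling Factors,
BRD1,BRPF1,23774,119.4,2,4,-19.2,Chromatin Remodelling Factors,
CBX2,CDCA6,84733,56,2,7,-12.2,Chromatin Remodelling Factors,
CHD5,CHD5,26038,222.9,2,2,-43,Chromatin Remodelling Factors,
ARID1B,BAF250B,57492,237.5,1,1,-1.6,Chromatin Remodelling Factors,
MSL3,MSL3,10943,58.2,1,2,-1.7,Chromatin Remodelling Factors,
POLE3,CHRAC17,54107,16.8,1,9,-1.6,Chromatin Remodelling Factors,
SMARCA5,SNF2H,8467,121.8,1,2,-27.6,Chromatin Remodelling Factors,
HDAC2,RPD3,3066,55.3,6,20,-51.8,Histone PTMs regulators,Ac
WBP7,MLL4,9757,293.3,5,4,-35.3,Histone PTMs regulators,Me
KAT6B,MYST4,23522,199.7,4,7,-29.4,Histone PTMs regulators,Ac
EHMT1,GLP1,79813,86.6,4,8,-27.3,Histone PTMs regulators,Me
ZMYND8,RACK7,23613,128.3,3,3,-23.9,Histone PTMs regulators,Ph
BRD8,SMAP,10902,94.2,3,6,-21.2,Histone PTMs regulators,Ac
MLL3,HALR,58508,541,3,1,-18.8,Histone PTMs regulators,Me
MLL2,KMT2D,8085,593,3,1,-18.7,Histone PTMs regulators,Me
HDAC1,SMAP,10902,55.1,2,8,-38.8,Histone PTMs regulators,Ac
SETD1A,KMT2F,9739,185.9,2,2,-14,Histone PTMs regulators,Me
SHPRH,SHPRH,257218,193,2,2,-11.6,Histone PTMs regulators,Ub
MORF4L1,MRG15,10933,41.4,2,11,-13.7,Histone PTMs regulators,Ac
EHMT2,G9A,10919,128.9,2,3,-13,Histone PTMs regulators,Me
BAZ1B,WSTF,9031,170.8,2,1,-10.9,Histone PTMs regulators,Ph
DOT1L,KMT4,84444,164.8,1,1,-12.2,Histone PTMs regulators,Me
CDYL,CDYL1,9425,60.6,1,3,-2.3,Histone PTMs regulators,Ac
SNW1,SKIP,22938,61.5,16,42,-161.7,Transcriptional regulators,
SAFB,HET,6294,102.7,6,17,-84.4,Transcriptional regulators,
NCOR2,SMRT,9612,272.7,5,4,-39.9,Transcriptional regulators,
SIN3A,SIN3A,25942,145.1,4,4,-38.6,Transcriptional regulators,
GATAD2A,GATAD2A,54815,68,4,9,-34.1,Transcriptional regulators,
NCOR1,TRAC1,9611,270,4,3,-35.7,Transcriptional regulators,
ZBTB4,ZNF903,57659,105,3,12,-18.9,Transcriptional regulators,
HP1BP3,HP1BP3,50809,61.2,2,6,-11,Transcriptional regulators,
DMAP1,EAF2,55929,53,2,5,-12.9,Transcriptional regulators,
SIN3B,SIN3B,23309,133,2,3,-10.9,Transcriptional regulators,
TAF1,TAFII250,6872,212.5,2,2,-10.7,Transcriptional regulators,
RB1,OSRC,5925,106.1,2,4,-10.4,Transcriptional regulators,
COBRA1,NELFB,25920,65.7,1,3,-3.6,Transcriptional regulators,
CBX3,HP1gamma,11335,20.8,1,9,-1.9,Transcriptional regulators,
ZBTB33,ZNF-kaiso,10009,74.4,1,2,-1.6,Transcriptional regulators,
TRIM28,KAP1,10155,88.5,1,3,-2,Transcriptional regulators,
HIST1H4L,H4,8368,11.4,2,33,-21.5,Nucleosome components,
HIST3H2BB,H2B,128312,13.9,2,25,-12,Nucleosome components,
HIST1H1T,H1,3010,22,1,14,-1.8,Nucleosome components,
H2AFY2,H2A2,55506,40,1,4,-2.1,Nucleosome components,
HIST1H2BA,TSH2B,255626,14.2,1,27,-1.9,Nucleosome components,
MTA2,MTA1L1,9219,75,15,31,-174.3,Others,
ACIN1,ACINUS,22985,150.5,8,8,-69.8,Others,
RBBP4,NURF55,5928,47.6,6,24,-59.7,Others,
SMC1A,SMC1,8243,143.1,6,8,-46.7,Others,
MBD3,MBD3,53615,32.8,4,17,-29,Others,
PARP4,PH5P,143,192.5,3,3,-19,Others,
NASP,FLB7527,4678,78.4,3,6,-19.4,Others,
C14ORF43,ELM2,91748,114.9,2,3,-12.1,Others,
BRCA2,FAD,675,384,2,1,-11.1,Others,
TOX4,LCP1,9878,66.2,2,18,-12.1,Others,
LIG4,LIG4,3981,103.9,1,1,-1.8,Others,
MBD3L2,MBD3L2,125997,23,1,6,-1.9,Others,
EIF2C1,EIF2C,26523,97.2,1,2,-1.8,Others,
PRMT8,HRMT1L3,56341,45.3,1,2,-1.8,Others,
PRMT5,HRMT1L5,10419,71.3,1,2,-1.8,Others,
HERC2,SHEP1,8924,526.9,1,0,-1.8,Others,
BRCA1,IRIS,672,202.2,1,1,-2,Others,
DICER1,Dicer,23405,208.3,1,1,-2.4,Others,
C6ORF130,C6orf13,221443,17,1,8,-2.1,Others,
EIF2C2,AGO2,27161,97.1,1,2,-2.7,Others,
TSPYL1,TSPYL,7259,49.2,1,9,-2.4,Others,
TNKS1BP1,TAB182,85456,181.7,1,1,-1.9,Others,
BRIP1,BACH1,83990,140.8,1,1,-10.8,Others,
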
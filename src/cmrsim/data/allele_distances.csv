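gene,distance,unit,note
Adh1-1F vs Adh1-1S (maize),2.02,percent_difference,
Pi-ta (rice blast resistance),1,amino_acids,
Pikh (rice),13,snps,
Adh1 (wild barley),77,base_pairs,digit grouping of the source extraction is ambiguous
Adh1 (wild barley),19,base_pairs,digit grouping of the source extraction is ambiguous
Adh1 (wild barley),45,base_pairs,digit grouping of the source extraction is ambiguous
Adh1 (wild barley),48,base_pairs,digit grouping of the source extraction is ambiguous
Adh1 (wild barley),54,base_pairs,digit grouping of the source extraction is ambiguous
Adh1 (wild barley),19,base_pairs,digit grouping of the source extraction is ambiguous
Adh1 (wild barley),56,base_pairs,digit grouping of the source extraction is ambiguous
Adh1 (wild barley),47,base_pairs,digit grouping of the source extraction is ambiguous
Adh1 (wild barley),19,base_pairs,digit grouping of the source extraction is ambiguous
HMGCR,0,synonymous_snps,
HMGCR,1,nonsynonymous_snps,
HMGCR,1,noncoding_snps,
HSD3B1,3,synonymous_snps,
HSD3B1,2,nonsynonymous_snps,
HSD3B1,1,noncoding_snps,
HTR1E,1,synonymous_snps,
HTR1E,0,nonsynonymous_snps,
HTR1E,0,noncoding_snps,
HTR2A,2,synonymous_snps,
HTR2A,3,nonsynonymous_snps,
HTR2A,9,noncoding_snps,
HTR2C,0,synonymous_snps,
HTR2C,1,nonsynonymous_snps,
HTR2C,0,noncoding_snps,
HTR5A,2,synonymous_snps,
HTR5A,0,nonsynonymous_snps,
HTR5A,0,noncoding_snps,
HTR6,1,synonymous_snps,
HTR6,0,nonsynonymous_snps,
HTR6,0,noncoding_snps,
HTR7,0,synonymous_snps,
HTR7,0,nonsynonymous_snps,
HTR7,0,noncoding_snps,
IGF1,0,synonymous_snps,
IGF1,0,nonsynonymous_snps,
IGF1,8,noncoding_snps,
IGF2,0,synonymous_snps,
IGF2,0,nonsynonymous_snps,
IGF2,1,noncoding_snps,
ITGA2B,4,synonymous_snps,
ITGA2B,3,nonsynonymous_snps,
ITGA2B,0,noncoding_snps,
ITGB3,4,synonymous_snps,
ITGB3,3,nonsynonymous_snps,
ITGB3,0,noncoding_snps,
KLK2,0,synonymous_snps,
KLK2,1,nonsynonymous_snps,
KLK2,2,noncoding_snps,
LCAT,3,synonymous_snps,
LCAT,0,nonsynonymous_snps,
LCAT,0,noncoding_snps,
LDLR,7,synonymous_snps,
LDLR,3,nonsynonymous_snps,
LDLR,0,noncoding_snps,
LIPC,4,synonymous_snps,
LIPC,3,nonsynonymous_snps,
LIPC,4,noncoding_snps,
LPL,1,synonymous_snps,
LPL,1,nonsynonymous_snps,
LPL,0,noncoding_snps,
MAOA,1,synonymous_snps,
MAOA,0,nonsynonymous_snps,
MAOA,0,noncoding_snps,
MAOB,1,synonymous_snps,
MAOB,0,nonsynonymous_snps,
MAOB,0,noncoding_snps,
MPL,1,synonymous_snps,
MPL,2,nonsynonymous_snps,
MPL,1,noncoding_snps,
NGFB,1,synonymous_snps,
NGFB,1,nonsynonymous_snps,
NGFB,5,noncoding_snps,
NT3,1,synonymous_snps,
NT3,0,nonsynonymous_snps,
NT3,0,noncoding_snps,
NTRK1,5,synonymous_snps,
NTRK1,2,nonsynonymous_snps,
NTRK1,0,noncoding_snps,
PACE,2,synonymous_snps,
PACE,0,nonsynonymous_snps,
PACE,4,noncoding_snps,
PAI1,1,synonymous_snps,
PAI1,2,nonsynonymous_snps,
PAI1,1,noncoding_snps,
PAI2,5,synonymous_snps,
PAI2,4,nonsynonymous_snps,
PAI2,5,noncoding_snps,
PC1,1,synonymous_snps,
PC1,3,nonsynonymous_snps,
PC1,1,noncoding_snps,
PCI,5,synonymous_snps,
PCI,5,nonsynonymous_snps,
PCI,4,noncoding_snps,
POMC,0,synonymous_snps,
POMC,0,nonsynonymous_snps,
POMC,0,noncoding_snps,
PRL,1,synonymous_snps,
PRL,1,nonsynonymous_snps,
PRL,1,noncoding_snps,
PROC,3,synonymous_snps,
PROC,0,nonsynonymous_snps,
PROC,0,noncoding_snps,
PROS1,1,synonymous_snps,
PROS1,0,nonsynonymous_snps,
PROS1,0,noncoding_snps,
PTAFR,0,synonymous_snps,
PTAFR,2,nonsynonymous_snps,
PTAFR,0,noncoding_snps,
PTH,1,synonymous_snps,
PTH,0,nonsynonymous_snps,
PTH,2,noncoding_snps,
PTHLH,0,synonymous_snps,
PTHLH,0,nonsynonymous_snps,
PTHLH,13,noncoding_snps,
SELP,5,synonymous_snps,
SELP,8,nonsynonymous_snps,
SELP,0,noncoding_snps,
SHBG,1,synonymous_snps,
SHBG,3,nonsynonymous_snps,
SHBG,1,noncoding_snps,
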
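value	attribute_type	synonyms
TP53	GENE	
PIK3CA	GENE	
KRAS	GENE	
MYC	GENE	
BRCA1	GENE	
breast cancer	CANCER_TYPE	breast
lung cancer	CANCER_TYPE	lung
mutations	DATA_TYPE	mutation
copy number alterations	DATA_TYPE	copy number|cnas
gene expression	DATA_TYPE	expression
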
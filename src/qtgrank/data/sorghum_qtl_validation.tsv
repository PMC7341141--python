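# Literature-curated Sorghum bicolor QTLs with cloned causal genes and
# the percent rank assigned to each causal gene by the published
# ortholog-trained sorghum model; used for external-validation arithmetic.
trait	gene_name	gene_id	genes_in_qtl	percent_rank
Light sensitivity	phyB	Sobic.001G394400	144	1
Brown midrib	bmr2	Sobic.004G062500	27	3
Amylose	Wx	Sobic.010G022600	706	3
Fungus resistance	Ds1	Sobic.005G065000	389	15
Plant height	Dw2	Sobic.006G067700	335	15
Seed shattering	Sh1	Sobic.001G199200	117	18
Aluminum tolerance	MATE	Sobic.003G403000	26	19
Light sensitivity	ghd7	Sobic.006G004400	115	61
Pollen fertility	PPR	Sobic.002G057050	26	69
Flowering time	PRR37	Sobic.006G057900	22	77
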
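species	lineage
Arabidopsis_thaliana	eudicot
Solanum_lycopersicum	eudicot
Brassica_rapa	eudicot
Glycine_max	eudicot
Populus_trichocarpa	eudicot
Oryza_sativa_japonica	monocot
Oryza_sativa_indica	monocot
Setaria_italica	monocot
Setaria_viridis	monocot
Sorghum_bicolor	monocot
Brachypodium_distachyon	monocot
Hordeum_vulgare	monocot
Zea_mays	monocot
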
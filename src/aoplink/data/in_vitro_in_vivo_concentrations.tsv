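chemical	cas	context	medium	scenario	value	unit	provenance
phthalic anhydride	85-44-9	in_vitro_epithelial	culture medium	16HBE14o 4h	1330	uM	epithelial toxicogenomics study
phthalic anhydride	85-44-9	in_vitro_dendritic	culture medium	MUTZ-3 24h	200	uM	dendritic toxicogenomics study
phthalic anhydride	85-44-9	in_vivo_biomonitoring	urine	occupational low	2460	uM	urinary biomonitoring, as printed
phthalic anhydride	85-44-9	in_vivo_biomonitoring	urine	occupational high	114800	uM	urinary biomonitoring, as printed
glutaraldehyde	111-30-8	in_vitro_epithelial	culture medium	16HBE14o 4h	190	uM	epithelial toxicogenomics study
glutaraldehyde	111-30-8	in_vitro_dendritic	culture medium	MUTZ-3 24h	10	uM	dendritic toxicogenomics study
glutaraldehyde	111-30-8	in_vivo_predicted	plasma	generic PBK Cmax low	0.08	uM	generic PBK model, dermal exposure
glutaraldehyde	111-30-8	in_vivo_predicted	plasma	generic PBK Cmax high	0.16	uM	generic PBK model, dermal exposure
2,4-Diisocyanato-1-methylbenzene	584-84-9	in_vitro_epithelial	culture medium	16HBE14o 4h	150	uM	epithelial toxicogenomics study
2,4-Diisocyanato-1-methylbenzene	584-84-9	in_vitro_dendritic	culture medium	MUTZ-3 24h	40	uM	dendritic toxicogenomics study
2,4-Diisocyanato-1-methylbenzene	584-84-9	in_vivo_predicted	lung interstitial fluid	40 ug/m3 air, 4 h	0.023	uM	PBK model output
2,4-Diisocyanato-1-methylbenzene	584-84-9	in_vivo_predicted	lung epithelial lining fluid	40 ug/m3 air, one inhalation	0.000575	uM	PBK model output
maleic anhydride	24937-72-2	in_vitro_epithelial	culture medium	16HBE14o 4h	2650	uM	epithelial toxicogenomics study
maleic anhydride	24937-72-2	in_vitro_dendritic	culture medium	MUTZ-3 24h	500	uM	dendritic toxicogenomics study
maleic anhydride	24937-72-2	in_vivo_biomonitoring	serum	occupational		uM	Unknown (serum MA-specific IgE antibodies detected; no quantitative concentration reported)
Trimellitic anhydride	552-30-7	in_vitro_epithelial	culture medium	16HBE14o 4h	2730	uM	epithelial toxicogenomics study
Trimellitic anhydride	552-30-7	in_vitro_dendritic	culture medium	MUTZ-3 24h	150	uM	dendritic toxicogenomics study
Trimellitic anhydride	552-30-7	in_vivo_predicted	plasma	inhalation OEL low	0.009	uM	generic PBK model Cmax
Trimellitic anhydride	552-30-7	in_vivo_predicted	plasma	inhalation OEL low	0.01	uM	generic PBK model Cmax
Trimellitic anhydride	552-30-7	in_vivo_predicted	plasma	inhalation high	0.17	uM	generic PBK model Cmax
Trimellitic anhydride	552-30-7	in_vivo_predicted	plasma	inhalation high	0.19	uM	generic PBK model Cmax
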
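# Literature compilation: mass-balance performance indicators of BSF larvae
# reared on chicken-type feeds, typically harvested when part of the cohort
# had reached the prepupal stage.  Values as printed in the source studies
# (2 decimals); 'derived' marks cells read from graphs or completed from the
# identities SCE = 1/SCR and SCE = BR/SRR rather than reported directly.
feed,xmax_ww_mg,xmax_dw_mg,br,sce,scr,srr,derived
chicken feed,,33.9,,0.23,,,
chicken feed,251,,0.13,0.15,,0.85,sce
hen feed,229,,,0.27,,,
chicken feed,,55.6,0.21,0.32,,0.68,
chicken starter mash,148.4,,0.18,0.35,,0.50,sce
chicken feed,,69,,0.34,,,
broiler feed,216.2,,,0.48,,0.44,
chicken feed,,66,,0.38,,0.66,
chicken feed,,,0.08,0.16,,,br;sce
chicken feed,191,,,0.27,3.75,0.64,xmax_ww;sce;scr;srr
chicken feed,80,,,0.14,,0.43,xmax_ww
chicken feed,,,0.18,0.41,2.4,0.44,sce;scr;srr
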
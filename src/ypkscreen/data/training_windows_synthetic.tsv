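protein_id	site_position	window
fpk1_class	37	RARSLSVKAL
fpk1_class	200	RGRTNSIDSA
fpk1_class	244	RQRANTVSPL
fpk1_class	436	RTRSASFGNK
fpk1_class	481	RSRAQSVKNE
fpk2_class	121	RERSNSIVAD
orm1_class	52	RDRSRSVSES
orm1_class	53	RPRSLSIESD
orm2_class	47	RDRTGSVEFD
orm2_class	48	RTRGVSNADN
gpd1_class	24	RSRSSSVASS
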
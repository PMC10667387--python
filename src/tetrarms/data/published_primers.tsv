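assay_id	primer_name	role	orientation	sequence	mismatch_positions	mismatch_types	target_allele	product_o	product_a1	product_a2
X221	Out-F67	outer	forward	GCTGATGCTACACACACGGAT				486	352	179
X221	In-F201w1	inner	forward	AGATGTTATCGAGGACGTCGC	3	C-A	C	486	352	179
X221	In-R247m5	inner	reverse	TCTGCACATTGAACATCTTCTATGA	2	G-T	T	486	352	179
X221	Out-R552	outer	reverse	TTCTGAGGCACAATCTGCTACC				486	352	179
X428	Out-F68	outer	forward	GCTGATGCTACACACACGGATG				549	213	383
X428	In-F403w1	inner	forward	GTCTTGACGAGTGAATCCATACATAG	2	A-C	G	549	213	383
X428	In-R450m6	inner	reverse	TCAAGGTGTCCAATGTCAGGCA	3,18	G-T,G-G	T	549	213	383
X428	Out-R615	outer	reverse	CTCACAGTTGCCTTTGTCATCCT				549	213	383
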
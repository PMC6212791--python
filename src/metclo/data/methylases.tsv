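name	class	recognition	meth_offset_top	meth_offset_bottom	modification	flags	empirically_blocks	synthetic
M.Osp807II	M	AGGTCTC	0	3	m6A	active_37C,single_subunit,orphan_no_restriction	BsaI	yes
M.Rsp7740I	M	GGAAGAC	2	-	m6A	active_37C	-	yes
M2.NmeMC58II	M	AGAAGAC	2	-	m6A	active_37C,single_subunit,orphan_no_restriction	BpiI	yes
M.SacI	M	GAGCTC	5	5	m5C	active_37C	-	no
M.AspJHL3I	M	MGCTCTTC	2	-	m4C	active_37C	-	yes
M.XmnI	M	GAANNNNTTC	2	2	m6A	active_37C,single_subunit,orphan_no_restriction	LguI	no
M.TaqI	M	TCGA	3	3	m6A	active_37C,single_subunit	EarI	no
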
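name	recognition	spacer	overhang_len	blocked_by
BsaI	GGTCTC	1	4	M.Osp807II
BpiI	GAAGAC	2	4	M2.NmeMC58II
LguI	GCTCTTC	1	3	M.XmnI
EarI	CTCTTC	1	3	M.TaqI
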
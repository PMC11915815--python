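cluster	og_id	sp_type	tm_count	expected_label
A	OG0001014	other	0	cytoplasmic
A	OG0001163	other	2	polytopic
A	OG0001473	other	0	cytoplasmic
A	OG0001162	Sec	0	exported
A	OG0001472	other	1	monotopic
A	OG0000796	other	2	polytopic
B	OG0001150	other	0	cytoplasmic
B	OG0001147	other	0	cytoplasmic
B	OG0001146	other	0	cytoplasmic
B	OG0000169	Sec	0	exported
A-B	OG0001148	other	0	cytoplasmic
A-B	OG0001149	other	0	cytoplasmic
C	OG0001210	other	0	cytoplasmic
C	OG0000094	other	0	cytoplasmic
C	OG0001176	other	0	cytoplasmic
C	OG0001177	other	1	monotopic
C	OG0001178	other	2	polytopic
D	OG0001213	other	0	cytoplasmic
D	OG0001214	other	2	polytopic
E	OG0000266	other	0	cytoplasmic
E	OG0000231	other	0	cytoplasmic
E	OG0000230	other	0	cytoplasmic
E	OG0000229	other	0	cytoplasmic
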
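protein_id	organism	sigma4_end	truncation_points	note
ecf41_Bli	Bacillus licheniformis DSM13	167	167;192;204	variant 167 lacks the whole C-terminal extension; 204 is hyperactive
ecf41_Rsp	Rhodobacter sphaeroides 2.4.1	169	169;206	variant 169 lacks the whole C-terminal extension; 206 is hyperactive
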
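category	arrows	count	p_ecf	p_coe
ECF_alone	>ECF>	126	38	NA
COE_up_same	>COE> >ECF>	107	0	97
COE_down_same	>ECF> >COE>	53	14	24
convergent	>ECF> <COE<	9	3	4
divergent	<ECF< >COE>	55	36	41
ungrouped	ungrouped	23	NA	NA
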
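>BLi01248 organism=Bacillus_licheniformis utr=142 function=hypothetical_putative_membrane_protein
TGTCACAAAAACATAAATAATAGATGTC
>Bli03073 organism=Bacillus_licheniformis utr=109 function=hypothetical_putative_membrane_protein
TGTCACCCCTTCCTT-TTTCGAGCCGTC
>hprP organism=Bacillus_licheniformis utr=163 function=putative_phosphatase
TGTCACGCTTGCTTTTATTTTTCTCGTC
>mtrB organism=Bacillus_licheniformis utr=76 function=transcription_attenuation_protein
TGTCACTTCAGCTGT-AAGGGGAACGTT
>nhaX organism=Bacillus_licheniformis utr=199 function=stress_response_protein tested=yes
TGTCACGTTTAGGTG--CTTTTGTTGTT
>pucR organism=Bacillus_licheniformis utr=39 function=purine_catabolism_regulatory_protein
TGTCACAAATCCGCT--CATTTTTTGTT
>sat organism=Bacillus_licheniformis utr=97 function=sulfate_adenylyltransferase
TGTCACAAGCGTTCTGCTGGCATCTGTC
>spoIISB organism=Bacillus_licheniformis utr=60 function=stage_II_sporulation_protein_SB
TGTCACAGAATTTGA-TTATCTCCTGTT
>uvrX organism=Bacillus_licheniformis utr=120 function=DNA_damage_repair_protein tested=yes
TGTCACCTTCTTTCC-AAAGAAGGTGTT
>ybxF organism=Bacillus_licheniformis utr=68 function=ribosomal_L7Ae_family_protein
TGTCACTAAAAATTG-TCATCATATGTT
>ydfG organism=Bacillus_licheniformis utr=31 function=putative_carboxymuconolactone_decarboxylase tested=yes
TGTCACAAACTCCGT-TTCTCTCTTGTT
>yfmE organism=Bacillus_licheniformis utr=42 function=heme_ABC_transporter_permease
TGTCACGGCAATGAT-TGGGACGCCGTT
>ykpA organism=Bacillus_licheniformis utr=108 function=ABC_transporter_ATP_binding_protein
TGTCACAAAGAAAGTGGAAATAAGCGTT
>ypbE organism=Bacillus_licheniformis utr=48 function=unknown_LysM_domain tested=yes
TGTCACGGCACATTTTTTGATCGATGTT
>yvdI organism=Bacillus_licheniformis utr=63 function=maltose_maltodextrin_ABC_transporter
TGTCACACTGCTCATTTCTTTCATTGTC
>gcvH organism=Rhodobacter_sphaeroides utr=151 function=glycine_cleavage_system_H_protein
TGTCACGTCCGGCG-GCTTCGGCCCCTC
>repA organism=Rhodobacter_sphaeroides utr=152 function=RepA_partitioning_protein
TGTCACCGTTTCG--CCCCAAGAACGTG
>rplL organism=Rhodobacter_sphaeroides utr=20 function=ribosomal_protein
TGTCACCCACC--ATGTTGGACCCCATC
>RSP_0606 organism=Rhodobacter_sphaeroides utr=32 function=putative_carboxymuconolactone_decarboxylase tested=yes
TGTCACAACCGC-CTTCCCTCGCCCGTC
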
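>IGHM_CH1_BALB|strain=BALB/c|gene=IGHM|exon=CH1|snp=rs29176517|snp_offset=291|snp_base=g
gagagtcagtccttcccaaatgtcttccccctcgtctcctgcgagagcccctgtctgataagaatctggtggccatgggctgcctggcccgggacttcctgcccagcaccatttccttcacctggaactaccagaacaacactgaagtcatccagggtatcagaaccttcccaacactgaggacagggggcaagtacctagccacctcgcaggtgttgctgtctcccaagagcatccttgaaggttcagatgaatacctggtatgcaaaatccactacggaggcaaaaacagagatctgcatgtgcccattcca
>IGHM_CH1_B6|strain=C57BL/6|gene=IGHM|exon=CH1|snp=rs29176517|snp_offset=291|snp_base=a|synthetic=single_snp_reconstruction
gagagtcagtccttcccaaatgtcttccccctcgtctcctgcgagagcccctgtctgataagaatctggtggccatgggctgcctggcccgggacttcctgcccagcaccatttccttcacctggaactaccagaacaacactgaagtcatccagggtatcagaaccttcccaacactgaggacagggggcaagtacctagccacctcgcaggtgttgctgtctcccaagagcatccttgaaggttcagatgaatacctggtatgcaaaatccactacggaggcaaaaacaaagatctgcatgtgcccattcca
>IGHG2B_CH1_BALB|strain=BALB/c|gene=IGHG2B|exon=CH1|snp=rs45969375|snp_base=c
gccaaaacaacacccccatcagtctatccactggcccctgggtgtggagatacaactggttcctccgtgactctgggatgcctggtcaagggctacttccctgagtcagtgactgtgacttggaactctggatccctgtccagcagtgtgcacaccttcccagctctcctgcagtctggactctacactatgagcagctcagtgactgtcccctccagcacctggccaagtcagaccgtcacctgcagcgttgctcacccagccagcagcaccacggtggacaaaaaactt
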
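>balbIGHV036|strain=BALB/c
caggttactctgaaagagtctggccctgggatattgcagccatcacagacgcttagcctggcctgtactttctctgggatttcactgagtacttctggtatgggtttgagctggcttcgtaagccctcagggaaggctttagagtggctggcaagcatttggaataatgataactactacaacccatctttgaagagccggctcacaatctccaaggagacctccaacaaccaagtattccttaaactcaccagtgtggacactgcagattctgccacatactactgtgcttggagagag
>balbIGHV037|strain=BALB/c
caagttactctaaaagagtctggccctgggatattgaagccctcacagaccctcagtctgacttgttctttctctgggttttcactgagcacttctggtatgggtgtaggctggattcgtcagccttcagggaagggtctggagtggctggcacacatttggtgggatgatgataagtactataacccatccctgaagagccagctcacaatctccaaggatacctccagaaaccaggtattcctcaagatcaccagtgtggacactgcagatactgccacttactactgtgctcgaagag
>balbIGHV038|strain=BALB/c|variant_of=balbIGHV009|label=G32A
aaggtccagctgcagcagtctggagctgagctggtgaaacccggggcatcagtgaagctgtcctgcaaggcttctggctacaccttcactgagtatattatacactgggtaaagcagaggtctggacagggtcttgagtggattgggtggttttaccctggaagtggtagtataaagtacaatgagaaattcaaggacaaggccacattgactgcggacaaatcctccagcacagtctatatggagcttagtagattgacatctgaagactctgcggtctatttctgtgcaagacacgaaga
>balbIGHV039|strain=BALB/c|variant_of=musIGHV398|deletion_nt=7
gaggtccagctgcaacagtctggacctgagctggtgaagcctggagcttcaatgaagatatcctgcaaggctactcattcactggctacaccatgaactgggtgaagcagagccatggaaagaaccttgagtggattggacttattaatccttacaatggtggtactagctacaaccagaagttcaagggcaaggccacattaactgtagacaagtcatccagcacagcctacatggagctcctcagtctgacatctgaggactctgcagtctattactgt
>b6IGHV040|strain=C57BL/6|extension_5p=27|extension_3p=3|matches=musIGHV269
caggttcagctccagcagtctgggcctgagctggcaaggccttgggcttcagtgaagatatcctgccaggctttctacaccttttccagaagggtgcactttgccattagggataccaactactggatgcagtgggtaaaacagaggcctggacagggtctggaatggatcggggctatttatcctggaaatggtgatactagttacaatcagaagttcaagggcaaggccacattgactgcagacaaatcctccagcacagcctacatgcaactcagcagcctgacatctgaggactctgcggtctattactgtgcatga
>balbIGHV041|strain=BALB/c|variant_of=b6IGHV040
caggttcagctccagcagtctgggcctgagctggcaaggccttgggcttcagtgaagatatcctgccaggctttctacaccttttccagaagggtgtactttgccattagggataccaactactggatgcagtgggtaaaacagaggcctggacagggtctggaatggatcggggctatttatcctggaaatggtgatactagttacaatcagaagttcaagggcaaggccacattgactgcagacaaatcctccagcacagcctacatgcaactcagcagcctgacatctgaggactctgcggtctattactgtgcatga
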
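>transcription_template 1271 bp: Pol II loading site, 8x64 bp molecular ruler, 601 NPS, crosslink stall site
AGGTCTCAGAAGACGCCCGAACAACAGACACAAACACCACGGCCGGCGAGCCAGACACGACCAATTATCT
ATGTAACTTGCCATATTCAGGATTATCAGTAGCGGAAGAGCGAGCTCGGTACCCGATCCAGATCCCGAAC
GCCTATCTTAAAGTTTAAACATAAAGACCAGACCTAAAGACCAGACCTAAAGACACTACATAAAGACCAG
ACCTAAAGACGCCTTGTTGTTAGCCATAAAGTGATAACCTTTAATCATTGTCTTTATTAATACAACTTAC
TATAAGAAGAGACAACTTAAAGAGACTTAAAAGATTAATTTAAAATTTATCAAAAAGAGTATTGACTTAA
AGTCTAACCTATAGGATACTTACAGCCATCGAGAGGGACACGGGGAAACACCACCAGCCTCCCGGGCTCA
CCATCATCCTGACTAGTCTTTCAGGCGATGTGTGCTGGAAAGATCTTATGTCACCCCGGGCTCACCATCA
TCCTGACTAGTCTTTCAGGCGATGTGTGCTGGAAAGATCTTATGTCACCCCGGGCTCACCATCATCCTGA
CTAGTCTTTCAGGCGATGTGTGCTGGAAAGATCTTATGTCACCCCGGGCTCACCATCATCCTGACTAGTC
TTTCAGGCGATGTGTGCTGGAAAGATCTTATGTCACCCCGGGCTCACCATCATCCTGACTAGTCTTTCAG
GCGATGTGTGCTGGAAAGATCTTATGTCACCCCGGGCTCACCATCATCCTGACTAGTCTTTCAGGCGATG
TGTGCTGGAAAGATCTTATGTCACCCCGGGCTCACCATCATCCTGACTAGTCTTTCAGGCGATGTGTGCT
GGAAAGATCTTATGTCACCCCGGGCTCACCATCATCCTGACTAGTCTTTCAGGCGATGTGTGCTGGAAAG
ATCTTATGTCACCCCGTGGATCCGCCGGCCGCAACGATGGACCCTATACGCGGCCGCCCTGGAGAATCCC
GGTGCCGAGGCCGCTCAATTGGTCGTAGACAGCTCTAGCACCGCTTAAACGCACGTACGCGCTGTCCCCC
GCGTTTTAACCGCCAAGGGGATTACTCCCTAGTCTCCAGGCACGTGTCAGATATATACATCCTGTGCATG
TATTGAACAGCGACCTTGCCGGTGCCAGTCGGATAGTGTTCCGAGCTCCCACTCTAGAGGATCCCCGGGT
ACCGAGCTCGAATTCGCCCTATAGTGAGTCGTATTACAATTCACTGGCCGTCGCACCCTGGTGTACAGAA
CGCAATGAATT
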
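>unzipping_template_stem 434 bp Y-stem with two tandem 601 NPS copies and end-hairpin stem
TTTTGACTACTGACGCGGACATTCAGGAGATGGACCCTATACGCGGCCGCCCTGGAGAATCCCGGTGCCG
AGGCCGCTCAATTGGTCGTAGACAGCTCTAGCACCGCTTAAACGCACGTACGCGCTGTCCCCCGCGTTTT
AACCGCCAAGGGGATTACTCCCTAGTCTCCAGGCACGTGTCAGATATATACATCCTGTGCATGTATTGAA
CAGCGACCTTGCAACGATGGACCCTATACGCGGCCGCCCTGGAGAATCCCGGTGCCGAGGCCGCTCAATT
GGTCGTAGACAGCTCTAGCACCGCTTAAACGCACGTACGCGCTGTCCCCCGCGTTTTAACCGCCAAGGGG
ATTACTCCCTAGTCTCCAGGCACGTGTCAGATATATACATCCTGTGCATGTATTGAACAGCGACCTTGCA
CCCTCCACTCTAGA
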
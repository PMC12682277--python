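>AKN1
GATCAGCTGATAGCTACCACAGTGCTACAGACTGGAACAAAAACCCTGCT
>AKN2
TAGCAGGGTTTTTGTTCCAGTCTGTAGCACTGTGGTAGCTATCAGCTGAT
>AP92
TCGACAGGGTTTAAATGAAGCACAGCAAAGAAATTAGAGCTACAAAAACATTGTG
>AP93
TCGACACAATGTTTTTGTAGCTCTAATTTCTTTGCTGTGCTTCATTTAAACCCTG
>AP94
GATCCGCTGTGAGCTGAGATCACTCCATTGCACTCCAGCTGGTGCAACAGAGCAAAACTCCATCG
>AP95
GATCCGATGGAGTTTTGCTCTGTTGCACCAGCTGGAGTGCAATGGAGTGATCTCAGCTCACAGCG
>AP96
TCGACTAGTGTTCTGTTAAGCACAGAACAATTTTACAGAACACAAGCATCAGACAAGTCTACTCG
>AP97
TCGACGAGTAGACTTGTCTGATGCTTGTGTTCTGTAAAATTGTTCTGTGCTTAACAGAACACTAG
>AP98
GATCCAAAGAACTCTACTTTCACCCTAATTAATACAAAAGGAGCCAATAATAGGAAAGACAAAATG
>AP99
GATCCATTTTGTCTTTCCTATTATTGGCTCCTTTTGTATTAATTAGGGTGAAAGTAGAGTTCTTTG
>AP100
TCGACAAACTTGGGACAGCCCACAGGTAGGAAGCAAGAGAAAGAAAAATAGAAG
>AP101
TCGACTTCTATTTTTCTTTCTCTTGCTTCCTACCTGTGGGCTGTCCCAAGTTTG
>DG13
GATCCCTCTAGACCGGTACTACTCGAGCCACACCCGCCCGCTGCACCCTCCTCCC
>DG14
GGGCGGGAGGAGGGTGCAGCGGGCGGGTGTGGCTCGAGTAGTACCGGTCTAGAGG
>DG27
GATCCCTCTAGACCGGTACTACTCGAGCGGCCCGGCGCTGCCAGCGCGGGCTCGG
>DG28
GGGCCCGAGCCCGCGCTGGCAGCGCCGGGCCGCTCGAGTAGTACCGGTCTAGAGG
>MS20
TTTTTTTTTTGACCATTGGCGATCTCAGCGTACGGACGACTTCGGATGACTTTTTTTTTT
>MS21
GTCATCCGAAGTCGTCCGTACGCTGAGATCGCCAATGGTC
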
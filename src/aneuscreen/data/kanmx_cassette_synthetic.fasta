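>kanMX_synthetic synthetic stand-in selection-cassette sequence (1500 bp)
AGTAGCCCTTCCAAAGGACAAGCTCCGTAGGAAACTCTCTCAAACTCGATAAACCTAAGTCTTGAGACAT
ACTGGCCATTCGATAATACTGCTTAGACAAATGCCTTCTGCGAAGTTGGAACAATGACTTTGAGGATAAA
ATATTTCGGGCTCAAGGGGCGAGAGTATCCTCGGGCTCACACAGCGACCATGCTAAGAAATGGCTCACCA
AATACGGGTAACTATCGATTGCATCTAAGGATCTAATATCCTCAGAGCCATTTCATGGACAATATTTGCG
AAGAGGAGCGGCTTTCTCGCTCGTAATTATAAACGACATCCTCTGGTCGCTTGATCCGTGGGCCCGGTCG
CAATCGCCCTCTGAGAGTGGTTTCAACAGGACATTGCTCAGGTCAGCATGGGGTAAGGCACGCCGTTGCT
TCGATAACACTAACAATAACGATTCCCTGCGAAATTACTGGCGTTGACAGAGCGCGCTTTGGGCCCGTTA
CCCCTATGTTGTTATGCCCAGAATCGTATAGTAAAGCACACTACCCCGGGTGAGAAGAGTAATTTCCGGG
AATAGCTCATACAGTGTAGTATTTTAATCCGCGTGTGTCGTCTCGTCGTGCGGCGTCCGAGCACGACGGT
TGTTTCGGGGTAAACTTCGTAAAACTGTGCGCCAACCGCCGTGAAGTTCTGCTCGATATTCGTCCGCACG
TTCAGTCCTACCCGTCCCCCTACTTATAAGGGATCCATTTACACTGTCTGTTCTGCAAGTAGCTCCATAA
TGACCCGGTCATCTTCGGCAGCCCGGAATTAAACAACGTACACGTACTGGTCGCTCTAATCCAATTAGGT
GAATAACGCCCGCAGCTGCTCCACGCGTCTTCTGAGGAGGAGCCAGATGTGGTGCTCATCGTCGCCATGC
CCAGGCCACGTTAGTCATGGAGCGTGAGCCTCGCACGAAATGTAACACGGTGCGTGTAACCGTGTCCAGC
TGCGTTTGCTAATGGCTATTAATACGAGGAACAGCCGGCCCTTATCGGGCCTGTGGTTGGCCTGTGCTTC
AAGCCAGCAACTAGACGTGTCACTGTCTGCGCGAAAACAATCAGGTACTCTTTGCCAAAAGTCTAGTCCG
ATGTGGGCGGACTATCTTTAGATTTTTAGGATATGCTTCTGTGCCTACGTTGCCAGTTAGGCTCTTCGAG
CTTTGCTGGGGTCTATTAGCTCGGGGAGATGCAGATTCTTCAAACGGAGCTTGTAGCACACGACTGGAAC
TTTCGGATCTGACCCGGTGCCTAAAGCTCGACCGAATACCGACTGTCGGCGCCTAGGCTTGCACGGTTTA
AAACATTACCCACGTGAATAAGCACAACAACTCATGGCGTTAGACTTTTCAACGACATGTATCGGCTAAC
GATAGAATACTGGTGCTTGGCTACATTTATAAGGCGCCAGAATCAGGGCTTTGTTCACAATGGCACGGAG
CGTCGCGAAGACATTTAGATAGCAAATTTT
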
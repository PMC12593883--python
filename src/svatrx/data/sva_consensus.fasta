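>D
CCCTCTGGGTGCGCGAACGCGCCGGCTCCTGGTGCCCAGGCCCTTAGGTATCATCCTCCCCCGCAACCAG
AGATAATCACCGGCGGACAGGTACCGTCGTCAAGTTCAATGGCGGGTCAGCTGCGGTCCAACCGTTCGAC
ACGCACAAAAATGTGCGCTATTAGCGTAAGAAGAGATTTGCCGCGCGTGTTGCCGGGGGGATCAGATCGA
CGCTCATAAAGGGCAGAGGTGGGCCCATACCCTCACAGCCACTTACGCCCGCGCCCCGGTGCAGTTGCGC
AGCCGTATATTGAGCAGATAACCACAGGCCCCCCCTCTGGCTGGCGCCATAGCGACGGCTCGGGGCCCCC
CCTCTGGCTGGCGCCATAGCGACGGCTCGGGGCCCCCCCTCTGGCTGGCGCCATAGCGACGGCTCGGGGC
CCCCCCTCTGGCTGGCGCCATAGCGACGGCTCGGGGCCCCCCCTCTGGCTGGCGCCATAGCGACGGCTCG
GGGCCCCCCCTCTGGCTGGCGCCATAGCGACGGCTCGGGGCCCCCCCTCTGGCTGGCGCCATAGCGACGG
CTCGGGGCCCCCCCTCTGGCTGGCGCCATAGCGACGGCTCGGGGCCCCCCCTCTGGCTGGCGCCATAGCG
ACGGCTCGGGGCCCCCCCTCTGGCTGGCGCCATAGCGACGGCTCGGGGCCCCCCCTCTGGCTGGCGCCAT
AGCGACGGCTCGGGGCCCCCCCTCTGGCTGGCGCCATAGCGACGGCTCGGGGCCCCCCCTCTGGCTGGCG
CCATAGCGACGGCTCGGGGCCCCCCCTCTGGCTGGCGCCATAGCGACGGCTCGGGGCCCCCCCTCTGGCT
GGCGCCATAGCGACGGCTCGGTAGTGCAATCGGCTCGATGGTAGACGAAGATTAGGTTGACTGCCTGTAC
ACCAGTGGTCTAAACCAGGACCTTTTAGGTTCACTTTACGCGGCGAGTGCGTTTTACATCTGGCTGCAAC
GGAGCAGTTGTGTGCACAGAGGATCCCTACGAAGAAAGGGATGCTGCGCCCGTCGATAAGTTTACATGGT
CGGGGGAGCGCGGACTTCCGGTATCTCGCGCAATGAAGACTGCAGGTTAAATAACCTGTGGAATCTCCCA
CGCGTATCCAGTCACATGTACGTGAACTTAAGGAAAGGGTCGCGTATACAATGGTGCTTACGTTCATCAG
AATCGGTACGTGGTCGTGGATGCGACGTTATTCAGCTCCAGTGGTATAGTAGCAAGTGTCAGCACGCCAG
GGTCGTATCCAACGGGTCGTATGGCGCACAGGAAGCTCATATGGACCGGTATTGTCGTGCTCCCTACAAG
CTAGGGAGCGTCCAAAATAAA
>E
CCCTCTGGGGGCGCGAACGCGCCGTGTCCTGGTGCCCAGGCCCTTAGGTATCATACTGCCCGGCAACCAG
AGATAGCCACCGGCGGACAGGTCCCGTCGTCATGTTCAATGGCGGGTCGTCTGCGATCCGACCGTTCGAT
TCGCACAAAAATGTGCGCTATTAGCGTAACAAGAGGTTTCGGGCGCGTGTTGCCGGGGGGATCAGATCGG
CTCACATAAAGGGCGGAGCTGGGCCCATAGCCGCACAGCCAATTACGCCCGCGCCCCGGTGCAGTTGCGC
AGGCGTATATTGTGCAGTTAAACAGTGGCCCCCCCTCTGGCTGGCGCCATAGCGACGGCTCGGGGCCCCC
CCTCTGGCTGGCGCCATAGCGACGGCTCGGGGCCCCCCCTCTGGCTGGCGCCATAGCGACGGCTCGGGGC
CCCCCCTCTGGCTGGCGCCATAGCGACGGCTCGGGGCCCCCCCTCTGGCTGGCGCCATAGCGACGGCTCG
GGGCCCCCCCTCTGGCTGGCGCCATAGCGACGGCTCGGGGCCCCCCCTCTGGCTGGCGCCATAGCGACGG
CTCGGGGCCCCCCCTCTGGCTGGCGCCATAGCGACGGCTCGGGGCCCCCCCTCTGGCTGGCGCCATAGCG
ACGGCTCGGGGCCCCCCCTCTGGCTGGCGCCATAGCGACGGCTCGGGGCCCCCCCTCTGGCTGGCGCCAT
AGCGACGGCTCGGGGCCCCCCCTCTGGCTGGCGCCATAGCGACGGCTCGGGGCCCCCCCTCTGGCTGGCG
CCATAGCGACGGCTCGGGGCCCCCCCTCTGGCTGGCGCCATAGCGACGGCTCGGGGCCCCCCCTCTGGCT
GGCGCCATAGCGACGGCTCGGTAGTGCAATCGCCTCTATGGTAGACGAAGATTAGCTTAACTGCCTGAAC
ACCAGAGGTCTCAACCAGGACCTTTTACGTTCACTTTACGCGGCGTGTGCGTGTTACAGCTCGCTGCATC
GGAGCAGTTGCGAGCCAAGCGGATCCCTACGAAGAAAGGGATGCTGCGCGCGGCGACAAGTCTACCTGGT
CGGCGGAGTGCGGACTACCGTGAACACGCGCAATGAAGACTGCAGGTTAAATAACCTGTGGAATCTCCCA
CGCGTATCCAGAGACAAGTACGTGTACTTAAGGAAAGGATCTCGTATACAATGGCGCTTACGTTGATCAG
AATTGGTACGTGGGCTTGGTTGCGACGTTATTCAGCACCAGTGCAATAGTAGCAAGTGTCAGCACGCAAG
GATCATATCCAACGGGTCGTATGGCTCACAGTAATCGCATATGGACCGGTATTGTCGTGCTACCTACAAG
CTAGGAAGCGTCAAAAATAAA
>F
CCCTCTGGGTGCGCGAACGCGCCGGCTCCTGGTGCCCAGGCCCTTAGGTATCATCCTGCCCCGCAACCAG
AGATAACCACCGGCGGACAGGTACCGTCGTCATGTTCAATGGCGGGTCGGCTGCGGTCCAACCGTTCGAT
TCGCACAAAAATGTGCGCTATTAGCGTAACAAGAGGTTTACCGCGCGTGTTGCCGGGGGGATCAGATCGG
CGCACATAAAGGGCGGAGGTGGGCCCATAGCCGCACAGCCAATTACGCCCGCGCCCCGGTGCAGTTGCGC
AGCCGTATATTGAGCAGATAAACAGTGGCCCCCCCTCTGGCTGGCGCCATAGCGACGGCTCGGGGCCCCC
CCTCTGGCTGGCGCCATAGCGACGGCTCGGGGCCCCCCCTCTGGCTGGCGCCATAGCGACGGCTCGGGGC
CCCCCCTCTGGCTGGCGCCATAGCGACGGCTCGGGGCCCCCCCTCTGGCTGGCGCCATAGCGACGGCTCG
GGGCCCCCCCTCTGGCTGGCGCCATAGCGACGGCTCGGGGCCCCCCCTCTGGCTGGCGCCATAGCGACGG
CTCGGGGCCCCCCCTCTGGCTGGCGCCATAGCGACGGCTCGGGGCCCCCCCTCTGGCTGGCGCCATAGCG
ACGGCTCGGGGCCCCCCCTCTGGCTGGCGCCATAGCGACGGCTCGGGGCCCCCCCTCTGGCTGGCGCCAT
AGCGACGGCTCGGGGCCCCCCCTCTGGCTGGCGCCATAGCGACGGCTCGGGGCCCCCCCTCTGGCTGGCG
CCATAGCGACGGCTCGGGGCCCCCCCTCTGGCTGGCGCCATAGCGACGGCTCGGGGCCCCCCCTCTGGCT
GGCGCCATAGCGACGGCTCGGTAGTGCAATCGCCTCAATGGTAGACGAAGATTAGCTTGACTGCCTGGAC
ACCAGAGGTCTAAACCAGGACCTTTTAGGTTCACTTTACGCGGCGTGTGCGTTTTACATCTGGCTGCAAC
GGAGCAGTTGTGAGCAAAGCGGATCCCTACGAAGAAAGGGATGCTGCGCCCGGCGATAAGTTTACATGGT
CGGCGGAGCGCGGACTTCCGTGAACACGCGCAATGAAGACTGCAGGTTAAATAACCTGTGGAATCTCCCA
CGCGTATCCAGGGACATGTACGTGAACTTAAGGAAAGGATCGCGTATACAATGGTGCTTACGTTCATCAG
AATTGGTACGTGGGCTTGGTTGCGACGTTATTCAGCACCAGTGGTATAGTAGCAAGTGTCAGCACGCAAG
GATCGTATCCAACGGGTCGTATGGCTCACAGGAAGCTCATATGGACCGGTATTGTCGTGCTACCTACAAG
CTAGGAAGCGTCAAAAATAAA
>F1
AACAAAGAAGGGCGGGACCCTTTCTCAGACCACGCTATACCGAGGCGATTTTCGAATAACGACAGCCTGC
CTGCTGGAGATAGAAGGCACGTCGCCTGGTGTCCCTCGCATGATAATTTAAGCGCACACAATCCGTCACG
GTAAGTAAGAGCAGCGCGCAAGTTTCCCCGGGTGAGATACGGCAGAGGGTCCACGGACTGTGCCCACCGG
TTAGAATTATTGTGCTCGCATACCATCGGCATTTTATACGTCCAATTGTAGGCATGAGATTCACCGTGCG
CGTCTACCCACCGCGGGTGTCGTCCAAGCGGGGCTACGTAAGGATCTGAGGCGTTTATTATAGTGTATTG
CCTGTGACTACCTACCCCCTCCAGGTACAAACGACGTGTTGCCGGGGGGATCAGATCGGCGCACATAAAG
GGCGGAGGTGGGCCCATAGCCGCACAGCCAATTACGCCCGCGCCCCGGTGCAGTTGCGCAGCCGTATATT
GAGCAGATAAACAGTGGCCCCCCCTCTGGCTGGCGCCATAGCGACGGCTCGGGGCCCCCCCTCTGGCTGG
CGCCATAGCGACGGCTCGGGGCCCCCCCTCTGGCTGGCGCCATAGCGACGGCTCGGGGCCCCCCCTCTGG
CTGGCGCCATAGCGACGGCTCGGGGCCCCCCCTCTGGCTGGCGCCATAGCGACGGCTCGGGGCCCCCCCT
CTGGCTGGCGCCATAGCGACGGCTCGGGGCCCCCCCTCTGGCTGGCGCCATAGCGACGGCTCGGGGCCCC
CCCTCTGGCTGGCGCCATAGCGACGGCTCGGGGCCCCCCCTCTGGCTGGCGCCATAGCGACGGCTCGGGG
CCCCCCCTCTGGCTGGCGCCATAGCGACGGCTCGGGGCCCCCCCTCTGGCTGGCGCCATAGCGACGGCTC
GGGGCCCCCCCTCTGGCTGGCGCCATAGCGACGGCTCGGGGCCCCCCCTCTGGCTGGCGCCATAGCGACG
GCTCGGGGCCCCCCCTCTGGCTGGCGCCATAGCGACGGCTCGGGGCCCCCCCTCTGGCTGGCGCCATAGC
GACGGCTCGGTAGTGCAATCGCCTCAATGGTAGACGAAGATTAGCTTGACCGCCTGGACACCAGAGGTCT
AAACCAGGACCTTTTAGGTTCACTTTACGCGGCGTATGCGTTTTACATCTGGCTGCAACGGAGCAGTTGT
GAGCAAAGCGGATCCCTACGAAGAAAGGGATGCTGCGCCCGGCGATAAGTTTACATGGTCAGCGGAGCGC
GGACTTCCGTGAACACGCGCAATGAAGACTGCAGGTTAAATAACCTGTGGAATCTCCCACGCGTATCCAG
GGACATGTACATGAACTTAAGGAAAGGATCGCGTATACAATGGTGCTTACGTTCATCAGAGTTGGTACGT
GGGCTTGGTTGCGACGTTATTCAGCACCAGTGGTATAGTAGCAAGTGTCAGCACGCAAGGATCGTATCCA
GCGGGTCGTATGGCTCACAGGAAGCTCATATGGACCGGTATTGTCGTGCTACCTACAAGCTAGGAAGCGT
CAAAAATAAA
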
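>M16_1
ATAGCTCCATTCACAAATTCGACAGGTGCCAGCAGCCGCGGTAATCGAATTGGGAGTAAGTCTAATCATA
ATACCTAACATTTCTATCTCGCATGCCGAACCTGCCTTCATCCATTAATGGCGAGAAGACACTTGGGACG
GCATGGTCAACAGGTCGATAGTGTTACTTACAGGCACTCAATTGTTAGCACTCAAGGCGTTTCGAATACG
TTAGCCAGGTTCTTAAACTTGGATTTTGATAGCGATAATCGTCCAGGGGCTCTTCTACAGAGCTTCATGC
AAAATCCGATTACACCCTTCTGGTCAAACGAATTGAGAAACTCCCCAGACGTGGGTCAACCGTTTACACT
CGCATAGCACCCATGTGATGTAACATTTGCCCGCAAACTTAAATAAATTGGCGGGATGAGATCGCCTACC
CCTGGCCAT
>M16_2
TTAGAATTCGAGATGGGTAAACGCCGTGCCAGCAGCCGCGGTAAACGTCCGCCGGAGGAGGCTCACCAGT
GAGTGGACGCCAGTCACGAGGATCACTGGGCTTTATAATAGGACCATCATGGTCTGCAAAGCTGAGTTTT
AGATGGGTTCTGGTGGCGAATAGACTTACTTAGCTTTTACGAACAAATCATCGAGTTCTTAAGTGCATTG
TCCCTAAGGCGTCCCGTATCTCTGGTGCTTTGGCACTAAGTGCAACAGATTAACAAGGCATCATCAGCCA
TCGGGATCGACCGTAACTTCCAGAGTCAGTTCTCTCGCTGCCCTCGGCGGAGTGCTTGGTATCCCGGCTT
AGTACGTTAGGACTATTTCGAAAAACCAATTCCGGCTGGATCGCTTTCTAAACTCAAATGAATTGGCGGA
CATCAAGCAATCTCCAGTTCGTGC
>M16_3
AAAGTTTTATTGCGTTAACATTCGGGTGCCAGCAGCCGCGGTAATGTTCACCTTTGTAAGCAGATCAATC
CATAGACATTAAGCGCGGATAAGCAAACTCTTTGGCGAGGAGGTATATCGCAGAATAGACGGGAGACGCG
GATGTGGCATGAATGCTCGTTTGTATAGAAGGCCACTACTTTCGACTAAAGGTGAGCTTTGGTGTTCCAT
ACACGTCTGTTAGACTGCGTGCATGTTCTCAAATTAATGTCTAGACCGCCGCCCGGGGACAGACCAAGAC
GGTCTGGGCTGTCCGTGACCGATGATTCCATGTTCAGGACTATGCCCATGCAACAGGTATTGAAAGTGGC
GTATATGTCACTCTTATCGGCTTCGTTCTTTCGCGTAAATAGAGTGCAGCATTTCCACATTGGAAAACTT
AAAGAAATTGGCGGCTGCATGAAATGGGCATGTGAATTA
>M16_4
TATGACAATCTTGTTCTTGGGGTATGTGTCAGCAGCCGCGGTAACGGAAAATTCCCGGCACGGCAGTTCG
GGAGCGGACTACCTCCGCTCCTGGTTGGGTTAAGGCTATACCGGCTTTTTAACTTACTTGGGGCGGGTGG
CAGCAAGAAGTAGAATGTTGTACCATCCGTCGGTGGATCCGACGGCATCCACGTAGGATATCTCGGTTGC
CTGTGTATGTGGACGGTGCATACCACCTGCTTCGTGTACCACAGCGATATTACAGCTCCTCTATTGAACC
TTGTCAGAGCTAAAAAGATGCATTCCAATCCTCAGGTCAGCGTACCAACGTACAGCTAGAGCTTTTTAGG
TCGCCCGCGGTGGGGCAAGGCTATGCGTAAGTTGTAGCACAGGAGCAAAGACAAATCGTTCGCCCTCCCC
AATGCGAATAAACTCAAATGAATTGGCGGTTTTGGCAACGTAGACTCAATGCTA
>M16_5
TGTGTTGCTAGATCGTAGAGTGAGGGTGTCAGCAGCCGCGGTAATATATAGGAGACTCAAACCACACGAG
ATTCAGACGGAACATCCCGGTGTTAGACCTAGGTTTTCGTTACCTTTGTACGGAGTGGATACATAGCTGC
AGCTGTAGCCGGTTGCGACTGAGGGCATAGTCCGGCCGGTTGACAAGATTTCTTTCATTCAAATTCCAGT
TTATCCCGCCCTTCGAGGTTGCAGACCCCTCTGCTCCAGCCAGCAGATACACACAAACAATAGTATCGGG
TACCCCTGGCGCCACTGGGACCCAAGACTCTCTAATATTTGCCCGGAGTCCATGGCATGACGCGAGACTC
AGTGTCCCTACCTGAGACCAGTGTCACAATATTTATCGTGGCGTGATAGGAGTTGGCTGCGTCCATAGCC
AGTGCATCTTTAGTGAGGTTGTCCAAACTTAAATAAATTGACGGTTTTTCCGAACTCTTGGAGTCGACA
>M18_1
AGTAGTTTCTCCATAATTATTAAGCGTGTCAGCCGCCGCGGTAATCACAGTGTCAGCGTTACCCTAGGAC
GGGGACCTCCTGTATATCCCTCATTAGGAACAGTTTACCGTATGCGGTACGAGATTGGTCCACGCAGGTA
AATAGTGACCGTAACCGGCTGCGGAAGTACGATTCTGTAGGGTGAGTCTCGGATCGAAGTACGCTAACTG
CTCCGAGTTGACAGTCAGCACCACCAGCATGCCAGATAAGACTATGTGGAGCAAATTTGTCGTACGTGGT
GGCAAAGCCACTGGCGACTCTCCATGCAACTTTTAACTCTACTGCCGGTTCGATAAGACACAAGGGGCGA
CAGTGTTATACTCCACCGACCAAGATACTGATGGGTCCATCTTCTGCAGGTATGGGGTAATTAATGTCCT
CCATGCACCACTGTGCGACTAAAGGGCCGTAGACCATCACCCCTAAGATGGTTGTAAGCATGTTCTGTTA
TTTAGGTTTAGGACGCATTGAGGCAATCAAATAGGACTGCGTGTTCAGAAGTTAAAGGAGGGGACAAGTA
GACTAAACTCAAATAAATTGACGGAACATTCCAGCATTCTAACACAGGT
>M18_2
TTCGGTGGATGTTCACACGATGGTCGTGCCAGCAGCCGCGGTAATTGTGCTCATCTTGCGCCATCTTTCG
ACTCGGATGCCTCCTACCACACGGTCTAAGTGGATACGCGAGAACGCATTCAGTGAGTCCTGTTCGCGCC
TACAAGTGCCAATTCAAGAAGACAGCCAGAACTCGCCGGTCAGGTAGACCCACTTGCGATGCTTGCTTTT
ACTGGATAAGTTTCGGCTCGGTTCGGCATGAATCTTAAGAACGAGGGACCAACGAACCCAGTACGACGCC
GGGCAAGTTTCCTCAAAGATCAAATATCCAAAGTTGTGTCGAGCATCCCATAAAGAGTTGGCTATTCTCT
ATGTATCCCCCGTTAACTAACATAAGCTGTGGTAGGCGAGGATTAGAGTTGATGGTTATCAAACTTATTC
GTGTAGTCTAAACGTTTCACAGTTAGGGACTCATGCCCCACTCCAGCCCTCTTTCGGTCAACGTCCGTGT
TCAAGTCGGTGAATGTTCGCCATTCGTCAGCCTTTTTAATAGACTCAGTCAGTAGTGTTTAGGCATCATA
GAGCCACTGACGTCAGCAGAAGCTCCCACTAAATAACTCATAGAAAACTCAAAGAAATTGGCGGAAATGC
AGCACGGGCAGATACCGCA
>M18_3
CGCGGAAAACAAGATGCGACTTGTGGTGTCAGCAGCCGCGGTAATATGTGTAAATCACAGGATGGCCGTA
TGCCCAGAAGACTCATCTGGCACTAGTTTGGCACTTCAAATGAGCTGGGTGGACGCGATCTGTTAAAGGC
CACCTGGCGGAGCTACTAGTGTTCAGCAGTAATCGAGTACATTATGACAGTCACGTGGCCGAGAAAAGAG
GAAACTTAGAGGAAAATAATAACCAGCTACTGATTTTCGGATGGGTAATCCGTCCGACAAAGAACGTTGC
CTTTAGGTGTGCTAGCAGTGTATCTCTGCTTACTGCCGTATGAGACTGTGCGTTACCCCGCTAGCGGGAG
TCTAGTAAAGGGCGAGCCGGGTCAACACCCAATATACCGTGCGAGCTCCTTCGTCTCAAGCGGGCCGGGA
CCATGTTCCTTGTACCAATGGTTTAGGTACCCGTGTCTTTATTCTCACCGCCGGTCAGCGTAATAACCGC
TCATGTCTATTCCGATCAAAGGTACACATAACCTGCGGGGGGTATCGTTGTAATGTTCTTAAAGTACGGG
TGGGACGTCTAGAGAATGATGAAGCTTAGACTGCGCGGGTTCAGAGCACCGATCAGTTAGTCCATTGTAG
TGGCTGCAAGGTAAAAACTCAAAGGAATTGACGGTAAAGGTAGTGGGCCAGCTTACGGT
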
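>POLE_CDS_synthetic synthetic 2286-codon coding sequence (deterministic stand-in, not the NM_006231 sequence)
GACCTTACAGCGGGCGGCTCTAAACAGTGCTGGTACAATTTATCCATGAATCCTCACATAAAGTTACGAC
CTGTAGATCCCATGCAAACTGGAGGGACCCCGCAGCGTGAAAAGGTACAGTCACAGACTACAGGTATGGG
TACCCTGGCCCCGCACGCCATTAATACATGGATCGTCGGCTCAATCGATTTCGTCCCCCCACCGATCGAG
CGTTACTACCGGTTCCCGCTGGATATACTTAGTGAGCTCTGCTTACTACCGACCCGTGAAAACGATGTAC
TTCTAAGAGGTCCCGAGCCACTAACCTTTTCCCTCTTAAACGAATTTTGGACCCTCGCACTGTGTAGAGA
GGTTGGCTTCGGGTTCAGTGGCAAGAACCCCCATGTCGGGAGGACCCCGTCCGTCTTTACATGTCGCCCT
ATCAGTCGGCGTACATCAGAGACCTGCACCTCGGGAGGACGCGATAATTTTTCGCAACGACGCGAGTTTT
ACTGCTCCGCTTTGAATCACTGCTCTCTGGTGTTCCCTCGACGGAAACACAATAAAAGCGGGCGACCTAA
TGATTGGCCCTTCGAATTGACCGTACGACTTCCCGCCCAAAATATTAAGCTTGCGCTCTCCTATCAGGCG
GCATCGACAGTCACGCGGCTCCAGTCAGTCTTACCAAAACACAATCTACGACCGAGTGTTTTCCCTCTAG
GCTGGAATCATGGGGCCCTTATAAAGCGGACTCTCCTATTTATGTGGTACTTGTTCCCTCGCCGACTTAA
GTTAGGCAAAGTATGGCTTGCCGCCAGTGTGGGGTCCCAAAACATAGAGTTTAAACCCATGGGGTCCTGT
ACTCGGCACCTGAAACCTAATTATGAGGAGAATACCTATCTGTATTTAACCGTCTTGTGGTGGGTAATAT
GGCAGCTACCTATCGCACTACCGTTAGGCGGCTTGGGCTTTAGTCAGAATGGGTATCCACAGACCTCTCC
TAAGACCGAGACATGGCGAGTCAGTTGCCTAAACTCTCATTCAGTGTATTACGACTTTATGTCCATTACC
TGTGTGTGCAGTCAGTCCGATATCTGTATACATCACCAGCCACACTGTTTACTAGTTACGGAGGTTGAGA
AGTCCATGGACAATAGACTACGATGCCTCAGACGACCCCCAATACGCTGGAGCTGGCAGTCGGTCGGAAT
GCCCTTACATTGCTTACACTATCACACCAGATTACGGCGCGAGGAGAAAGCCTATCATTTGGACCTCGCA
CAAGCTTCGAGGACGATACCATTGCCTCGTCATCTTCGCGCCGTCTGGTGTAATTTCGTACGACAATCAT
TGTACTCATTAAGGGGGACACGGGCTAAAGGGACTTTCATACCGCAACGGTTGCATGGGGTGCGCCATTC
ATCTGAAGCTAGAGTCAGAAATCTATCTAAATTGGACCTATCCCAAACATTTACCACGTCTTCAAGTATC
ACACTAACAAAGTTATTGTTAGAGGTATTGGTGTCCCGTATCCCAGCTAATCGCGGCGTTGAAGACCTCG
TAGACTCGCCGGCCGGGTCATTGGAAGGCGGAAGATGGTCAATCTCTAAAAAGGCCAAGCATCGTGCCAG
TCCGTTCCGACCCCGTTGTCATGGTAGGGGCAGTGATTGCCGCCCATTGCGAAGTACGGTCGCTGGCTCC
TCGGTCCTTGTTCGTCTCTTCTCCTCCACTTTTCCCTCGTATCTGTTCACTGGCGGGAGTGCACACGAAA
CCAGGCTTTGCGGATTTGAATCCGTAGGCGCGAAACGAATGACGTCTCTCGGACTTACACGGGTCGGGTC
CAACTTGAAAACGCTTGCGTACAAATGGAGATCCAGGTCTTCACTAGAGCAGAGCCTATCACTTGCTCTG
GGGTTACAGATTAGTCCCGGTGTCAGGCCACAGCTATCGCCGATCTGCGCGGACTCTCATAGGACTAGTA
TTAGGCAGCCTGGAGATACGGTTTCAGGGCCCTTACTGCCGACACACCGGATTCCTTATCGTCTCATACT
TTGGAAGTACACCTTCTTCTTCTTATTACTCCGAGCAGTCAAGGTCGATAGCCTAAATAAGTCCTCAGAT
TCTAACTTTTCTGTGACCCGGACGGGTGAGGGTGTTGGTCCGTCAGACGTGGGAAAAACCCAGAGAGACC
ACAGGGGTCAACCTCTTATTCGAGGCAGGGCTTACGAAAGCTGTCTCTACAAGCTGTTTATGCTGACGGT
CTGCCATTACGACAATGTGGGCTATTCGTGGTATCCTTATCTGACCCCACAGCGGATTGACCCTCACATT
AAAACTGTAAGCCCGACACCGCGTAACTGGATGAACCGGTTCTCCACAACGACAGTGGCTCTACCGAAGA
GGGGTTCGAATTGGAGAGCGATGAGCCAAGTAAGGTGCGACTTGCTCGCGTCCATCCAGAATTTGGCATC
GCACCCAAGCGGTTACCTCCAAACCATCTTAAATACATATGACTCGAATCTATACTTGCCTTGTAAAGGA
CCGTTATATACACCGAAAACGCTATCTGGTACGCCTGGGGCGCACTATAGCGCCGTCAGTTATCGCTCGT
ACAGGAACTTGGTCTTAAGCTCGGCGCGGTCCACCTCATTGGATCTGATTGGAATATTTCGCCGGGGACT
AACCTCTCGGCAGGCCCTGAAGGAAGCATCGAGGATACGGCTACACAACTGGTACTTTGAGTGGAAGACT
CGAGCTAGCCCGGACGCCGGTGCTTTCTATTTACTGACGGTGCAATCTGATCAAAGTACTAGACCATGTC
TTTCGTCTGACATACTCTGGCTAATAGGATCGCAATGCCTTCCTTGGGTTGAGCACCCGACGAGCGATGG
TCACTGGCTTGCGTGGCGCACGGTTTATGTGACCTCCGTGCCCGGTAATGGCCGCGGTGCATGCCTGTTG
GGAGGCTCGAACTCTCAGTACCGGAGAGCCAGGGTCATGTATGACTGTTGTTACCCTTCCGGCTGTGACG
TTTCGGACGCTCACAGGCTCGATCCTCTAGCCCAACGGCCGTTTCTAGATTGGCTCTATCTGGGTCTGTC
ACCTTTGCATGCATTTTGTCACGCGCCGGTGAAACTGAGCCAGTTGCCCGTGTGGCAAGGACACCCTTGT
CAGGGTAAGAGGACATCGTTAGCGATAGGGCCGAAGTTCTATTCGTCCCTGAGCCTGGTCGCGTTTCCTA
CGGCACAGAGGATTGATCTGCGATTGAACCGCGTTCGATTTGCGAGTATTTGGCTGCATGGTAGCGCCAC
ACTTTCCGAAAAACGTGCCTTAACACGACCACATCAGTTGCTAGACTTTGGAGCACTCGTCCCAAATAAT
AGTATAGCAGCTTCTCTTGTCGAAGGTAGATGTCAACTTTACCTAGATTATGTCAAGACAGATCCAGAAA
GAGATCCATTTATTGCGGGGATGGCATCCGCGAACCGCCAGAGAAGAGGTCCATTGGAACTGCATCAATC
ACGCCCTACACTTCCAAAAGGAACTTCCATGATCGGCCCTGTACATCATATCCGAAAGAACCAGTTCGCA
AAGTATGGACCACCCATATCGTTTTCACTGATCAAAGTAAGCCGATACTTGAAGTCTTTGCGTACATCCA
AGGTTGTTGTCGCGGACCTTATGCGAGTGCGGATATGGCCGAGTCCCAGAGTTCCTCCATCTAAAAGCCC
TATACTTTGTTTGACACAGCTCCGGTCGGCTTACCTTACGGAAGGACCTGAAGAGCACTACCAACAGAGT
GACAACCTCAACCCCAGCCGCTTGCTACTCTACACTAGGGCATACAATCCCCCTTCCACGAGGAATTGGA
TCACTAGACGCGTTGGACTATGGCACGGACTCCCGAGATTTGTTATTACACAGCCGCACTACACGATCGT
TAACCTCGATGGGTGTGCGCTAGGAATCATAGTCGAGTTGTGGACCGTCACGACGTCTGAGTTAGTTCAA
CTAAGACCTCCACCACTGGTAGTGTGGCTGACAAATTCGGGGGAATACGACATTTATCATCAATGTCTTC
GGGCGACGACTCTGAGCGGTCTTAATCCTGAAGCCGGCGGGGAAGAGGGAATAAGGGCGTGCCTTCCAGC
TGGGAATCAAATTTCTTTCCGCAAAAGCACTCTTCTATATAGCACTGCTTGGGCGACCTATGTATGTTTA
ACTGAAATCGGGTTGTCACGCGAAGTCGCGTCTATATTGTATACCACAGGCACGGAATCTTACCAGGCTC
AGGGTTTCCTACCTTTTTTAGAATGCAGCCCCTATAGCGGCGCTTATAGACGGCGGTTCAAACGTACTTT
AATGGTAGCCAATCTTGATCACGTCACCCCGATGGATGTGCGTCGTTTCAATGTGCCCCGTTGGGGCCGG
TTAATCGCTAGATATTTGTTGCGCGTACTCGTAGTGCAAGCATTGCCGGCGCTGCGCTCCGGCACCCAAG
TTAGCCTGTCAGTTCACCGAATAATCGCGCGACAGTCACGCCTCTACGTAAGCTATAGATTTCTGAAAAC
CAAATCAATTGAACGTGTGCGACCCAAATGTCCCGGAGAAGACAGTCTTTGTCTGGTGTTAGATCCCCAA
CGCTTAAAAACAAAAGCGCTCATGGAGTGTATCACTAGAGCATTTGGGCTCTTGTGTAAGTTGATGCGTC
TCCCGCCCTATAACTACATAGCACTCTCTCCCAACGCGCTACAAGGAAATAACGGGTTGCACACAGGGAG
AGAAAGGTGTTGCCAACGGGAAAACAAGAAAATTTCATTCGAAAAATTTATCCCACGGGCGTCAGCGAAG
ACTAGCCGCAATCTGAAAATGCGCAAGGTGTGTCATTATCCCAGCGCTGGCACCCCACTTGCCGAATCGC
TTAGGTTCTCCAGCGAGACACACGCGCGCTCGCTACCGCATGATGTTTGCGGCTTATACACGGAAAACCT
GTTTGGACGAAGGGATCAGAGAAACGCGTTGCCCTCAAGGGGTAAACCAGATTCTAGTATTCCCCTGCAC
ACACGGATTAACAATGCACATAGAAGGCTTGCGTGTTTATCGTGGCGAGGCTACGGCTCCGGAGCCAATG
AGTTTATCAACCCACCCTTAAGCAGCCTCTCAGCAGATCTAGAACCTGTGATCGCCTCTGCGAACCTGAC
TAGCCTTCGTAAAACTGCCAGTGAATGCGATTTGTTCATAGGAGTAGACCTGTCGTGCAAGGCCCCCAAA
AATGGTCATTGCAAGCTGAGGGGGCCCCACAGCTCACCGCAGGTAGGGCCGGCAAATGGATTGTTCTACT
CTCTCTTATCAATTAGTGTTGCTCATAGTGGAGAGCCCGTGCTTCCTGCGTACAACGTGATACGAGGGAA
TACCAGCCGCTATGTCAAAGCTTGCGTGAGTTCAGCGTCCACTTCAATTGGAAATTATCGGAAGATGATC
TCTCATCGAGAAAGCAACGTAACAGGATGGGTCTGTACGACGGCATCCGAAAGCAAATGCGTGACGCTTA
CGTTTCAGGGGCTATTGCCGTCGATTTCATTAAATGTCCTATATCTTCAGGATCTGCATACGAGCTATAC
CCAGTGCGATCTAAACTCCTTAGACTATGTATCATGTTACCAACTCTTTGGTTTCTCCTACAGGGTGTTC
AACGACCACAATGCAGGAACGCCGTGCGGGATTCCCATGAGTGGACTAAGGGCATGTTCAGCGACATGTA
AACACTTTCAGGGACCACGCGAAGTAATGAACCAACGGGCGGTCTCCAACTCGAGCAATGGAAGTGCCGC
TTGTAGCTGGTTCAGCAACTCCATGCGGGTAATAGGTGTCCTCTTCACTGCTTACCGTCCTTACGGCTAC
AGCCCCTCCGAACCAGAGGTACTCCCGGAACTGACCACTGCGTTCCAGCGATGCACCCACTTGCCTGATT
GTTTGCCCGGGACGCCCAAACGGAGCGGATTCGGTTGTTTTAAGTCTACAAGACAGGAGAATGCGCTTCG
TACGCAACCTATAGAACCACCAGTCCTCCTCGCGCTATCTGTCATTCCAGCACAGTACAACCGTACCGCA
AACCGATACTCTGCGATCACAGTAGAGATCTCGGGCATGAATTCCACCCCCTCCCGGAAGTCAGGTATTA
GCACGGCATCTGTCGCCACGCTCATTACTGAGTTACATAAGCCATGTAGCCGTCGGACGAGCACTACAGA
AGTCTACCATACCAACAGCGAGTGCTCGTCGCCGGGAACGGTAACCAAAAGTCCCACTTCACGGTTTAAG
GGTACCGGATGTGGTCTATTGTTTAAATCATATGTGGACTATTATCATCTGCCGCGGGGTCCACCCTTAG
CTTGGAAACTGTTGCGGGGCGGGTTCACTCCAAACCGTAATTTTCACTTTCCGCAGCATACACCCTCGGG
TCCGCATCGCAATCGGTACGGGAGCGATTCTCTTTGCAGTGGCGCCCAGCAGTTTAGGAGGAGCACGCGT
GATCTCGAGAGTTCTGCATCACTTATGGCATTTCCCAAGGCCACCTCCGCAGTTTCTCAACAAAAAGCTC
AGTTTCGTTTCCACCTACAACTACCCACACTTAAGGCACAGTCCGGATCAGTTGGGAACTCTGGATGGGT
TGAAATGAATGGGAGTCTTGAGACCTTAACGCACCGTAGTTATGCATTCGACACGCCCGCGCCACTTGCG
CATGAAGGCCCCTTAATCAAAGGGTTGGAAACCAAATGCGGAACTGCTCCCTCTATCAGAGCGCCGATGG
ATAGTTTACGTAAAGTGATCTCGACGCCTGAATACGCGGAACAGCGGCGAATAGCCCGATTCCCTGTATA
A
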
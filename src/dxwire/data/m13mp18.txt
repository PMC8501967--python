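# M13mp18: deterministic surrogate scaffold sequence, 7249 nt
# (length-faithful stand-in generated from a fixed seed; replace with
#  the authentic sequence for wet-lab use)
TTTTATTCAATTGGTATTATTCCTTAGCCTGCTGTATTGCCACTCTCGCGCTGATGGTCAGAAGGGTGAG
AAAGTCAAATAGGCCGTCGATGGGCGTGCTTTGTTCTCTGGGCAGGGCCAGCACATAAGTCTAGGAATCA
TCCGACGCGCTAACGTGTGAGGGCCCCTATCGAGTTCCTTTGTGACCGCTACTTTCAGACCCATCCTAGT
GCCGTTGGAGACCGGTCGGTGCCCGCTCTTGCTATGTCTGACTTGCGGAGACCTTACGTCCAAAATCTAT
CCCCTAGCGCCATCATGGGCAATTTAGAAATTGTGAAGCGCGTAGGCCTTGTCGCAGCGGGTTCACCGGT
TACGCGTCTCGTTTAACAGCCCCATCTGAGATCTCCAGTGTGGGCTTTATCCTAGCGTGCAGGGCTAACT
GATGGGGAACTCGCTACCTAGCCGCCACAGCGGACAACATCGAGGACGCCTAAAGAGGGGATACGGGGAG
GTTATGAAGGTCACCTCAGAATACTCCATGCGGTACGATTTCGGGTCTTACCCCTTGCACTTCACAGAGG
AAGCACGGGCTATTCTTGGCCTGAATCGTCTGAGAACCTTGGGAGAAGGATGCGGCCCACGAATACAGCA
ATCGACGTCTACCCATAAATGTCAATGCCTTTTAACATATCGTATGCACCGACAACCAGTCCCTAGCAGC
AATCAGTATTAGGATCATTCCAACACCCTAGCACTGGTCGCAAACCATGATGCCCAGGTTGTCACACAGA
GATGCCAGATCTAAATCCCAAAGATCTCGAGTTCAGCCATATTCCAGGGCAATCCGAGCATTACGTGCCT
GTGAGTTGAGAATGCGATCCTAGGCCGCCGTAGATTTTTTTCACAAGATTGCAGAACACCGCTATTAAAG
CGAGCAAGGGAGCGTGCCGGAGCCCTCCCAGGCTGAAATCTCCAACGCAAAGTCACAAATCGAGCCATGG
TTGGCGCGTCGCGTGCGAGCTTCCGGATCAAAGATCGAGGCCTAAGATTTGCCGGGTTCTGCGAGCCCCT
AGAATGTGCCTGCAGGAACTGGGTCAAAATAATCGTGTCAGACGCAGCTAACTTTGGATAATCGAAGGCT
CTCGCAATAGTTCCGTGTACTATGAAACAAGCGCCGCGTAAGATTCAATTCGAAGCATCGCATCAAGTCT
GAACAGTGAAATCGAAATACAGGGGTTCCCGCTTAGCGAGCCATCTACAATACCCCGGTGACCTCAACTT
GGTGTGAAAGCGGTAATCCTACAGTTGGGGTGTCTGGGTCTCGCAACATTGCTGGGCCACTGGCCGGGCC
CGACTAGGGTTGGCGGAACGGCCGCTTGCTAAGCGGTAAGTCTCAACGACGCTAGCTACTATTTAAGCGT
GTCAGGGGGCACCCAGTCCGTATGCTTATAGGAACGTAACCCTATCACGGGCGGTGTAGTGCGGGTAGAC
TTACCAAGTCGTAACGCCAATCCTGTCGTGGTCTGGCACGAACATGCGGACGCGATGCTTGACGGACCCC
GTGTAGGAAAGAACCCTCACATACAGTCCCCGCATACGAGTACCTATCTGAGGCTTGTCAGTGATTAGTT
CCTTTCGGGGGTAGACTAAGCGGAGGTCTGCCGTGGATATGAAGCTAACTCCCGCAAGGTCGCGTTAGAA
CGCTACTCGTAAAAACTTGATGGGTACTTTGACCCCGGCAGCCACGGAGTACTACCGGCAGAGTTGTACG
CAGTGTTCGACGCGTCCCGAATGATCCCTGGATACGAAAGACTTCGCCGCTGAGCGAACTGCTATGGGGC
TGCAGACAATAAGGTGCGGCCCCTCCTAGCAATATAAGGGCCAATATGTAGTTGGGTTTATGGCCTGGCG
CCATCGAATACTGTAGATATGGGCTGCGGACGTTGTCCATGATCAACCGTGAGATCCTACTCGCCTTCTG
CTCAATTCGGCAATTAATTGGGCGCATGTAAAATAATTCAAGCTTCTCTTCACAGTGTACTACAGGGTAT
TTCCTCGGTTCGATGCCCCAGCTGATAAACGAACTCCTTTATGACCCTAACCTAAAGGCCACCCCTCATA
CAAACGGGTAGCCAAGCTTATTATCTCGCGAACTTTAGATCATTGGCACGGGTGTAGTACGTTTAAAGTA
GCATTGCGCCGCTAGGGTGCGCTTCATGGTAATTATCTAACGTTTTTATTTAAGCTTTCTGCATATCGGG
AAGCTTTGCTTTAGACAGACGACGCGGTGGACCCAGGAACTGCTGCACCGGGAGCTCCATTGGCGAAGAA
TGTGCCCTCTGGCCTGGGGTACGCGGAGGGTTTGACAGCTAGAGTGCACAAGTACTGGATGGCCATGCAT
GGCTGGACTTATGTCGGTGAACTAAGTCTCTCACACAGGCTCTAGAGAGCCAAAATGGTGTTGAACCCTT
GGATCGGCTGTCCGGGTCAGCAGTGAAGTCAAAGGACAACTTTAAAGCCGGGTTACTCGTTCAATAGATG
CCGAGCAAGGGGGGGTCGGACACTCCGTCACTAAATTCGGAATAGGCCGACCAGTCGACTGAAGGCCGAT
GCCAGGTAGCTAGACCGCACCTCGAAAAGACAATTTTGACGTCGCCAGCTACTTGTGATCCTGCTACGTT
ACAGTTCGGTAGACCGGCTTCGTGGTGCGGGGGTCGTAACCATACATAAATACGACCCGAAGTCCGTATA
TGCGAGATCCAACTCCGTTAAATATTTGGGATATCCGACGATCGAAGGTGTGTGTTACTCAAGGTCCTTA
TGTTTCAGATGTTACGACACACTTCGGCCGCAATTTGGCAGGTACATCAATGAGTGCATTATATTAGAGA
AGGTACGTATCATTCCCATAAAAATGCCAATCTAGGGAAGTGTTTCATGAATGCTATCGTAACATTTGCC
ATCGTAACAGTCCCCCCACTCTCGCTCCCGAGAATCCCAAGGAATTTATGGCGTACCTTAACTACAAGAT
GAAAAGACTAGGCCTTGATGCGTTCTGGTAGGGAGCGGTCGGCACGGCCTGGCCTCAATCCATAGCCTGA
TTACGATGTAGAGTACTTCGACACAATACAGATGCTGGTCCCGGGCAGTTGGTATGCCAGGACTTGGGGG
TCGAATCTGCTTGCTCTCTCGCATCATCGGGGACTGACATCGAAACATAGATTGAAAAGTAAAAGGGCTA
CGTTCGCTGGCAATTGAAACCATCACTTCAAACACTGCCGCTTTGACCGACATATCATAAAACGCATCTA
TCTGTTCGCAGCCCTCAGATAGATTACTCAAGGCGTTTGCCAATTGGTCCTTTGCTCCTCAGGGAGTCAA
GATTTACTCTCATATCATCGCAGAACCCCTACTGATCCGATAGGGGACCCCAACATACATCAAGGGCAGT
GCCCTCATCGCGATGCGGCCCCATTAATCTCATCACCATCCGCCTCAGATGGGAACAATACCCAACTCCA
ATGGAACTTAAATTACGAAACGATATCTCTATGCGGGAACACCTGTTGACAGGGGCATTGATCCGGGCTG
ATTACAGACGTCTTTCCAACTGCTTTTCCACGAGATAACTTGCGCTAGGTCGTATGAATGATATGCTTCA
TCCGCTAGTCGACACTATCGGGGCAGGTCATCCTTGTGCACCGCTACGGACTCCGGGCCAATACTGACTG
CTAGCCACGAAGTCGAGTATGACGCTTCCGGAAATGGCAAGCTGCATACACGGAGCTCACATGTAGCCCC
CTTATGATACTACAATGCTCGTTGTACAATAGTGCTGTGACATTACAGCAAACCATATACCGAACAACCC
GTGCGTTGCATCTCAGAAAGATTGCCAGTCCGGTACTTCCTTCCTTGACAGGGCGAGCAATATATTAGTG
CATCGGCGATTGTTCGGCAATTAACCACAGGTACGTACGCGTATCCGCCGACGGGATGCTACAATCATTT
TGGTCGTACGTCGTATATTTGTTCTCGTATGCACAGGACTGTCCTTGGGGGAGCTACATCTATTCACGTT
AAACTGTACGCACCATATGCGTACAATATTTCAGATCTTTCTTCTGTTCCTTGCTTTTGGTTCTTTCGTT
GTTACGCCTAGCCTAACGAATTAGCTTGAAGTGAGAGCGAGGTGACGCCAACAGCAAACCGACAGGATTA
TTCAGAATGCGTCCTAAGCGCGTCCGGTCGATGGCGATAAAGGCTCATCCCTTGTTCCAACCTATATTGC
GCGTTAGCATCGCCTAGGTTTTCCCGGAGGAAAGCTGAATTCCTTGTAAACATGGCTGAACAGCATACCA
GTAACCGCTTTAGACCCCCCGTCTGACTAAAGTCAAGGGGGTAACTTTGGGGTATATGCCAGTCCGGGGG
AGTTGTCGAGAACGTGTGCGCCCATGTTTGTAGAGAGATATAGCCAAGTTTTTATAGCCCATGTCCTAGC
ACACGTGGGGCTCAACAGTCGTTCGGATATACGGGGGGCTTTTTACAGCTAAAAGGGAGAACGGTGCGTC
GGTACACTTAGCAGAAGATTCAATTTTGCTCATTAGGACACTGAGAAGCGTAATTGAAGAGCTCGGCTCT
CCCGCGCAACGTGGCTCCCCAGGTCAGCTCTTTACGTTCTGGCATGGAGGACAATATTTTATACCCGGAT
CATCTCGACAAGTGAGAGATGCTCTGACTATGCGGATCAATCATTGTAAGCCTAGGACCGAACATTAACA
GATCTGGCAACAGGAAGGGCGCGACCTCTAACACTGTGTGCTGCTGTTGGGGAGGGCGTTGAATACTAGC
GTGCACTCCTTTGGGATATGTATAATAGGGTGACGCATACCGCGGGACCTTACCCGTACCCCAGTTAAAT
AAGTGGTCGACGCACGACGGGGTTCCCCAATCTTATACCTATGGGGGGCAGCCCGAGTACTAACCCCATC
CCTATTAAGCCAGTTTTCGACAGCGGGATGACCGTTTAAAGCCCTACAGAGTCACAATGAATTACTGTAG
GTGAGTTTCTTAGGTTCGGCGAAAATGAAGATCTCCGGATGGGACCCCTCCACCCATGCTACAGAAGTCC
TCGGGTGAGTGGCCTGGCGAAGTACTCACGGATTTTGGTAAAAAATGAGACAACGAGCATCGGAACCGGT
CTAACGTCGGTCAATTTCACAAGGCGTGTATGAAGCGGGGACGTTTCTACAATACCCACCTTATGTATGT
GTCCTACGCGACCCGACCCGGGAACCAGTTCACCGAGGCGTACTTTAATGTATCAAAGGGTATCCATGTG
CTGCGTGGTTGTCCAATTGCCGATTACCGCCATGACCCTGACACAGTGACCTGACGAACGGACTTTAGCG
TCGGGTTCTGCTCTGCACGTACGACATCCCGTACGGGTAGGGTGCGGTGAATGAGCTCAGGCCTACTATA
CTTTGATGGAACGCGGAAAAATACCACCGACTCGGTCGAGAGCAGATGAGTACTTGTCCCGCGAACGACG
GGAAACCTGTATGTCTCCCACGGGGAAGATCGCGCTCAGATTTGGTAAATTTTGCCACCCTACTGTTTAA
AGGCCGGTGTAATTGTTTTTTCTAGTAGGTGTTAGTATCACGATGCGCAATCCGTCTATAATGTTTCGAA
CTTTAGGCGCTAGTGGCCGGAGAGGCTTATCCGGCACCACCCGCCTTGCTCCAGCGTGGATCTGTAGCTC
TCTCGGTTTGCTTCGTAATTACCACTCACACATTCAGAGTACTTCCGCGTTACTATCTAAATCCTTTTCT
TGGAAAATCCCTAGCAGGTAATCCCAAGAAAACGGGTCTGAAGAAGTCTCTACAGATTGGAATTATGATT
GTGACGCTGCTACTGCGCACCCTTTACAGTTTACTGTTGCTTCGCCAGTTTACATAATCCGCGCGTTCCG
TAACCGCCTCCATGTTCCTGGTCTTTAGAGAATCGTGGACGTTCGTAAGCGACGTACGCCACTAGGCCCC
TTTGATGTTACTAGTGCTGCTAAAGCCCCCGTGCTTTCTCAGCTCCTATCGGATCGCTTACTATAGTACC
AATGCAATGTCTCGAGCCCATTCTCTGATCAGAAGCGATTGCGAATCTGTTCTCATCACGCCTCACTAGT
ACTCCGATTTGGACGGATTGGCATTGATCGGAGTGTCCGGGATGACGAGGGAGCGCCGCGGCCCGCCTTT
GCTCGCTCATTACAAAAAACAGACGGTAGATAAGCGGCATAGGGCGGGAGCGGCAGTGGGTGTAATTAAC
AGGCACGGATATGCGTGAAGGTTAACTCGCATGGGAATAAGACGGCACCACTGAACGATTAGTAGTTAGC
TCCCTAGCGGTGTATAGGCGTGACTGCCGCGGGTCTTGGGACCCTTTAATGGAAGACTCGACTTTAAAAT
ACCTACAGACTGTTAACTTCAGGGGCTCGCAGCAGATCTTATAGGGCTCGATAGTTACGTATTGCTAGGG
ATGCCACTCAAGCTATCTTGCTTCCGCCATTTGTTAGTTAGCAGAGACACACACAGACTTAGTACTGTGG
ACTCTGGGTGCTAGAGTTAAAATGGGGGGCAGAGCTAGTTACTATGCTACGATTCTAGCAAGGGGCTCTA
TTCTTGGTCTAACTACTCGTTGTTATGCGCTGCAGAAGTGAGCATGAATGCCTATGCTACCAGCACAGCC
TGACGGACAGGTACCACTTCATTACACTGTAGTGCCATCTTGTGAGTGATAGATCTCGCTTCTTAGGAAG
GTGTGTCGTCGTTCTTTTCAGTGGCCTCTTCCGCGTGACCCCCCCTTCTTACAGTCAAATGCCGGCCCAG
CGGACGGAGGCTTTTTCATCATCGAATACCGCCTGGATTTATCCGCATTTCTAGAGATAGAAAGAACACG
CTCGCCGTCTATCGGAAAGGGCAGGTTTCCAAACTCCGAGTTTCTACGCGGGTACGCTGGGGGTTCCTAA
ACGTACGAATGTCCTAATATTCAAGAGGAGCTCTATTGCAAAGAGTCTTTCCATGCTAGCGTGAATTATT
CCCTTCACTGGAATCGGAAAGCATCCTAGCCTCATAGCGAACGGGTGGGTGTAGGACCGGAGCGTGGACA
GTGTCCCTCGGTTTGTAGCGTAATTTTCTTTAAAAACACGAGCCCTTCGGATGCCGGGGGTCCCCTAAAT
TAAGCGTGTAAAGTGAGTTCTTAGATACTATATGCAGGC
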
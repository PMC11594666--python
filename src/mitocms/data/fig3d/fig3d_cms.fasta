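>fig3d_cms
TTAGTTAGTTAGCCATTTACGCTTGCTCGAGCGAATCCTTACAGCGAAAAAATAGGCGGGGGTCAAGGGC
GCAGGAAGATGTTGTCAAATTACTTCTTAGAATCGCACCCTGCACGGTCGATATCATGCAGTGATAGTTT
AAATTTCCTTTACTGAGGGACGAAGATCTGGTTTATGATCGAGACCGGTGTTGTGGGTATCACTGATGTT
CTATACAGTCATCTACCCCACAGCGACAATCGAATGGCTGAGCACCTCCAAGCTAGTTTAATCCAGGGAT
TTAATAGTGTTTCACGATTGAACTAAATACATGATATCTCATAAAGGCTGCTCATTTTATTATTTTCCTT
ACCATGCCCGAGGTTTAGGAACTCTAATAATTTCCAACGTGTAGCGCACGAAGTTATTTTTTTTAGTTAG
TTAGTTAGGTGGATCCGCACCCCTGAATACATTCTGCAGCGACGCTGACTCTGTTCAACAAGGTAGGTCG
CTTCTTATATTGAAGGAACGAAAGCGTCCGAACAGGCCCAAACTCGGATGATTGGGAATATAGAAGCAAA
TTAGGATCCAACGTACCTATACGTATCTGTACAATCGATACAGTGTGATACCTTTCTATTGGCACCCGAT
CAGACCGATGGGATCGTAAAGTACATCCGTATTTACGGTCACTCTCTCCACAATAAAACTTTATAAGTAT
ACCTAGATGACAGTCATAAGCTAGCGTGCGCATGGTATAACTATTAAGGCTTGCATCGAGTTCAAGAAGC
TTTAGGTTAGACATACACCTGCAGATGACTGTGTACAGACAAATATCTAAACAAATGGACTTAACCTGCA
TATGCAACGATCTAAGAGTACTTAGCAATGTAGGCTGATAGTAGACCGAAAGATCTCGCTCTTCCAGAGT
TAGGGTGCGTATGTTGTAGAGGCGATCACATCTACCCCCGCCACTACTTTCTTTCAGAATCGGCACTAAC
ATTTATTAGTTAGTTAGTGTGAACATTTGAGCATTTTGTCCCGATGTCGAGTCAGGGAGCAACCATAATT
CTTACGTAGAATGGTTAAGGCACTAGATCAGTAGTGAAAATTTATGGTTTCTTGTTTTGAATCCCTCAAT
TGAAATAGTGTCGCCAGTGGCTCGAGAGATCCGAATATTAGTTAGTTAGATGTTATCTAACTACTTATCT
AACTACTTATCTAACTACTTATCTAACTACTTATCTCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGC
TGCTGCTGCTGCTGCTGCTGCTGCTGCTGTTATCTAACTACTTATCTAACTACTTATCTAACTACTTATC
TAACTACTTATCTAACTACTTATCTAACTACTTATCTAACTACTTACTGCTGCTGCTGCTGCTGCTGCTG
CTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGTTATCTAACTACTTATCTAACTACTTATCTA
ACTACCTAAATGAGCAGCAGCAGCAGCAGCAGCAGCAGCAGCAGCCCTGAATCTAACTACTTATCTAACT
ACTTATCTAACTACTTACAATACAGGAGCAAAGGTTACCAACTAGTGGTTGCTGATTCGATACTACCACG
ACTTGCTATCTCACCTAACCTAGGGAACGGGTCCCCTAACGGACAGCTTGGCGTATGGGATGCACATACA
TTAGGCTATGTTATGCTTTTTGTTGCTATACTAATAGTCTGGGAGGTGTCTATAAAGATTTGTAGAATTT
GCTGGACACGGCTCTCTGCAAACCGGTTTTTCTACCTAGGAAAACACCTTACATTCAAGACTATAGACAA
GCAACAGTATCGCAAAAGGTCCACTGATACTAGTTATATTTTAATGTGGCAGAACCAGCTAATAGCAGTC
TTAGGTTGTGGTTCACTAGAACTGCAAACTTTGAGGCCTAAGATAAACCGGTTGATTCCTACTGGAATAG
GAGATCGAATAACAGTTCTGGCGGTTGCTGTTGTTATTCTCGAGCTGTCGCACACTATACGGTTTGTATC
GCCGGGGATAGTGCATTCTGGAACTATTATTTTTTTGAGGTTTGCTAATGCCACCACACAATGGAAAAAT
GCCTTTGGAAAGGATATAGACATAAAATTACAACAATGGAAGCGTTCCTTAAAACGAATGCTAAGATTAT
CCAACAATCAGAGAAAATGCTACACGCTATATCCAGATGGTGGTGAATTTCCAACCGAAAAGCCTAACAG
GGGGCTCGAACAAGTCCATGTGATCACTAGAGACGACGTACGCTTACGTGAGCCAGACACAAGGGCGGTT
CTCATAGTCCAGGCTGCCTTGCGACGGTGCAGCAAAGTAGTAATCAAAGTGAAGCGTAGAAGTTTTATAC
AGAGAACCCAGATACTTGTAAGGAGACAGATGGAGTTGGGACACAAGGTTCTTCCTAAAAAGCGTAAAAT
AAGAGTTGTAATCGGTAGGTACCAGATGGAAACGACCGGTCTGATCAGATTAGGAGAGCTACGTCAGAGA
TACCCCTAATTAGTTAGTTAGCAGGTAGCGTACGGACGCCTACGTGGGCTTTTGGAAGGGGTAGACTCTA
ATAAACCAGGCATCCAACTAGATCTGCCGATAATGCTTGAACACACAGGGGGCCCCCAGCGAGAGTGAAT
CTATGAGATTAATTGTCCCTCGGACCCGGTAAGTATGGAACTGCCTCTTTTCATCTGGTAGTAAGATCTG
GGAATGACATCAACCAAATCGTTAGTTCGTCAAGCGCCAGTTCCTCCCACCTACCTCCCCGGCCTTCGTT
GTTATAACTCCAGGTACATAGGTTTTTGGTTCCCATGTGAGAGTACCCCCTCTGCATAGTAATGCCATCC
GGGCGCACGTATGCCTTAAGCGGTACTATACTTTGCTAACAAGGTCTTGAATTGTCACTGTTTACCCACG
CCGTACTTAGAATGGACTCTCTCCGATAAATTGTAGAGTTATGTCCGCGACGGTTGAATTCAAGAATAGA
CTCTAGCCTAAATTAGTATGGCCCCCGTTTTAAGTACCAAAAACAACATAATTGATAGTGACAGGTTTCG
GTCATTGATTTCCAATCTTGGGCTTGTCTACACACGATCGTTGGTAGTAGCAAGTAAGTTGTGCCGTACA
GGGCTCATGGAGAAGTTACAGCAAAAATATATCAAAGATTACGGGGCGGACGCGCCCGAGACGTTTGCGC
CTTTAGCCGTATCCAACCGGGTTAGTTAGTTAGATGTTATCTAACTACTTATCTAACTACTTATCTAACT
ACTTATCTAACTACTTATCTAACTACTTATCTAACTACTTATCTAACTACTTATCTAACTACTTATCTAA
CTACTTATCTCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTG
CTGTTATCTAACTACTTATCTAACTACTTATCTAACTACTTATCTAACTACTTATCTAACTACTTATCTA
ACTACTTATCTAACTACTTATCTAACTACTTATCTAACTACTTATCTAACTACTTATCTAACTAATTAGT
TAGTTAGTTACAGGACTATAATATCTCCACCACCGATTCAATATGAGTATCTCCCGTTCGACTTGGGACC
ATCGTAAGCACGTACAGGACCGCGTCAAAGGAGCATCTATCTATTCTAACGGTTAAAAATAAATACAAAG
TGCGGTAAATGTAGAATCCATATGGAAACGTATATGATTTGCACTTATGTCCAGTGACTGTTAATTCCTC
TAAATCCAAGCTTACCAGGATACCGGAGATCGTCAATCCTTGCGGACCGCCCATAAACGCAATTCCTAGC
TTCTAGGGGAGTGCAACCTTCTGATACCCTGGTATATATCTCTACAGCGGGTCTAGCTAGACTGCAGGAC
ATGACAAAGCCTGCACAATGATACTTCAGATTAGAGCGCGCCCTGTAGTGGTTACGGGTGCAGTTAGTTA
TGCAGTGGTCTCTCAAACGCTACTCTCTGAGTGTTTCGCGCATAGTCTCTAAGGATCTAGTCTAGCGTGC
GTTTACTGAAGCTCACTAAAACCCTAATGCAAGAAGGCTAAAAACACGCTTATTTGGAGGTTTCTATGCT
TTTTGTTTTACCGTGTGCTTAGGTTCACCAGTCTAAAGGTCGTGGTCAACTCTTCTAACTGAGAGGGTAC
ATTTAACGTGAACAGAGCAGAGATAACGTTCGGAATTGTGTCCGGCTGCTTTTTGAAACAAGCAATACTC
AACAACACTACTCGAACGCTAAGTCCTTTATGAAAACTGGTAGTAGCGATACCTATGAGACATCCGATGG
AGTAGGGTAGCGAATCTAAAGGATGATCCTGATCCCGTTAGTTAGTTAG
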
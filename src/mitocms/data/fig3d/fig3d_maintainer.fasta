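>fig3d_maintainer
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
TGAAATAGTGTCGCCAGTGGCTCGAGAGATCCGAATATTAGTTAGTTAGTAAATGAGCAGCAGCAGCAGC
AGCAGCAGCAGCAGCAGCCCTGAATCTAACTACTTATCTAACTACTTATCTAACTACTTACAATACAGGA
GCAAAGGTTACCAACTAGTGGTTGCTGATTCGATACTACCACGACTTGCTATCTCACCTAACCTAGGGAA
CGGGTCCCCTAACGGACAGCTTGGCGTATGGGATGCACATACATTAGGCTATGTTATGCTTTTTGTTGCT
ATACTAATAGTCTGGGAGGTGTCTATAAAGATTTGTAGAATTTGCTGGACACGGCTCTCTGCAAACCGGT
TTTTCTACCTAGGAAAACACCTTACATTCAAGACTATAGACAAGCAACAGTATCGCAAAAGGTCCACTGA
TACTAGTTATATTTTAATGTGGCAGAACCAGCTAATAGCAGTCTTAGGTTGTGGTTCACTAGAACTGCAA
ACTTTGAGGCCTAAGATAAACCGGTTGATTCCTACTGGAATAGGAGATCGAATAACAGTTCTGGCGGTTG
CTGTTGTTATTCTCGAGCTGTCGCACACTATACGGTTTGTATCGCCGGGGATAGTGCATTCTGGAACTAT
TATTTTTTTGAGGTTTGCTAATGCCACCACACAATGGAAAAATGCCTTTGGAAAGGATATAGACATAAAA
TTACAACAATGGAAGCGTTCCTTAAAACGAATGCTAAGATTATCCAACAATCAGAGAAAATGCTACACGC
TATATCCAGATGGTGGTGAATTTCCAACCGAAAAGCCTAACAGGGGGCTCGAACAAGTCCATGTGATCAC
TAGAGACGACGTACGCTTACGTGAGCCAGACACAAGGGCGGTTCTCATAGTCCAGGCTGCCTTGCGACGG
TGCAGCAAAGTAGTAATCAAAGTGAAGCGTAGAAGTTTTATACAGAGAACCCAGATACTTGTAAGGAGAC
AGATGGAGTTGGGACACAAGGTTCTTCCTAAAAAGCGTAAAATAAGAGTTGTAATCGGTAGGTACCAGAT
GGAAACGACCGGTCTGATCAGATTAGGAGAGCTACGTCAGAGATACCCCTAATTAGTTAGTTAGCAGGTA
GCGTACGGACGCCTACGTGGGCTTTTGGAAGGGGTAGACTCTAATAAACCAGGCATCCAACTAGATCTGC
CGATAATGCTTGAACACACAGGGGGCCCCCAGCGAGAGTGAATCTATGAGATTAATTGTCCCTCGGACCC
GGTAAGTATGGAACTGCCTCTTTTCATCTGGTAGTAAGATCTGGGAATGACATCAACCAAATCGTTAGTT
CGTCAAGCGCCAGTTCCTCCCACCTACCTCCCCGGCCTTCGTTGTTATAACTCCAGGTACATAGGTTTTT
GGTTCCCATGTGAGAGTACCCCCTCTGCATAGTAATGCCATCCGGGCGCACGTATGCCTTAAGCGGTACT
ATACTTTGCTAACAAGGTCTTGAATTGTCACTGTTTACCCACGCCGTACTTAGAATGGACTCTCTCCGAT
AAATTGTAGAGTTATGTCCGCGACGGTTGAATTCAAGAATAGACTCTAGCCTAAATTAGTATGGCCCCCG
TTTTAAGTACCAAAAACAACATAATTGATAGTGACAGGTTTCGGTCATTGATTTCCAATCTTGGGCTTGT
CTACACACGATCGTTGGTAGTAGCAAGTAAGTTGTGCCGTACAGGGCTCATGGAGAAGTTACAGCAAAAA
TATATCAAAGATTACGGGGCGGACGCGCCCGAGACGTTTGCGCCTTTAGCCGTATCCAACCGGGTTAGTT
AGTTAGTTAGTTAGTTAGTTACAGGACTATAATATCTCCACCACCGATTCAATATGAGTATCTCCCGTTC
GACTTGGGACCATCGTAAGCACGTACAGGACCGCGTCAAAGGAGCATCTATCTATTCTAACGGTTAAAAA
TAAATACAAAGTGCGGTAAATGTAGAATCCATATGGAAACGTATATGATTTGCACTTATGTCCAGTGACT
GTTAATTCCTCTAAATCCAAGCTTACCAGGATACCGGAGATCGTCAATCCTTGCGGACCGCCCATAAACG
CAATTCCTAGCTTCTAGGGGAGTGCAACCTTCTGATACCCTGGTATATATCTCTACAGCGGGTCTAGCTA
GACTGCAGGACATGACAAAGCCTGCACAATGATACTTCAGATTAGAGCGCGCCCTGTAGTGGTTACGGGT
GCAGTTAGTTATGCAGTGGTCTCTCAAACGCTACTCTCTGAGTGTTTCGCGCATAGTCTCTAAGGATCTA
GTCTAGCGTGCGTTTACTGAAGCTCACTAAAACCCTAATGCAAGAAGGCTAAAAACACGCTTATTTGGAG
GTTTCTATGCTTTTTGTTTTACCGTGTGCTTAGGTTCACCAGTCTAAAGGTCGTGGTCAACTCTTCTAAC
TGAGAGGGTACATTTAACGTGAACAGAGCAGAGATAACGTTCGGAATTGTGTCCGGCTGCTTTTTGAAAC
AAGCAATACTCAACAACACTACTCGAACGCTAAGTCCTTTATGAAAACTGGTAGTAGCGATACCTATGAG
ACATCCGATGGAGTAGGGTAGCGAATCTAAAGGATGATCCTGATCCCGTTAGTTAGTTAG
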
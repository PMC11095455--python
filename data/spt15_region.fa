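>SPT15 YER148W chrV:465303-466025(+) plus 500bp flanks
ATACTTGTGAAATACTAAGTTTGTCGCCAAGATTTTCCATGAATTTGTACTTCTTTCGAA
ATCGTTCAATTTCTACCAATACTGATTCCCCTCTGATAGCTGAGATGTCGGGATTCCCTT
TGCTGATAGATCTAACTCATCTCTTTACGTATTTTAATTGTGAAGCCGTAAATAGTTATC
TTCCAAGTTTCTCTTACGCGAGCTTTTTGGGAAAAGAAAAAAATTTGAAGATCTACATAT
AAAACATGGCTTCAAAGGATTACTAATGACTTTTTTTACCTTGATAGGTATTCTTGATGG
TAAGAGTAAACAAGGGACGTGAAAATTACAGTAGTTACTGTTTTTTTTGGACTATAAGAT
CGGGGGAAAGATAACACATAAGAAATAAAACGACTACTAGTTAGACTGCTCTGCGGAAGA
AGCAAGGAAGTAAAGGCTGCATTTTATTTTTCTTTTCTAGTCCAACATAAACAGGTGTAT
CAAGAGAAACTTTTTTAATTATGGCCGATGAGGAACGTTTAAAGGAGTTTAAAGAGGCAA
ACAAGATAGTGTTTGATCCAAATACCAGACAAGTATGGGAAAACCAGAATCGAGATGGTA
CAAAACCAGCAACTACTTTCCAGAGTGAAGAGGACATAAAAAGAGCTGCCCCAGAATCTG
AAAAAGACACCTCCGCCACATCAGGTATTGTTCCAACACTACAAAACATTGTGGCAACTG
TGACTTTGGGGTGCAGGTTAGATCTGAAAACAGTTGCGCTACATGCCCGTAATGCAGAAT
ATAACCCCAAGCGTTTTGCTGCTGTCATCATGCGTATTAGAGAGCCAAAAACTACAGCTT
TAATTTTTGCCTCAGGGAAAATGGTTGTTACCGGTGCAAAAAGTGAGGATGACTCAAAGC
TGGCCAGTAGAAAATATGCAAGAATTATCCAAAAAATCGGGTTTGCTGCTAAATTCACAG
ACTTCAAAATACAAAATATTGTCGGTTCGTGTGACGTTAAATTCCCTATACGTCTAGAAG
GGTTAGCATTCAGTCATGGTACTTTCTCCTCCTATGAGCCAGAATTGTTTCCTGGTTTGA
TCTATAGAATGGTGAAGCCGAAAATTGTGTTGTTAATTTTTGTTTCAGGAAAGATTGTTC
TTACTGGTGCAAAGCAAAGGGAAGAAATTTACCAAGCTTTTGAAGCTATATACCCTGTGC
TAAGTGAATTTAGAAAAATGTGATGGGGAAGGAGTAGACGAAAAGAAAAAAAGGTTTTCT
ATTTGTTCCATTTTCTCAATTATTAATGGTCCTCAAAGAAATAAAAGAAAAGGAAGAAGA
AGTAATTGTAATATCAAACGGTTTTTTATAGTATATTCTTCTTATTCTATATTTATATAT
CAATGTTTTATAATAAGATGTTTATTCATAGCATATCTGGTGGATCGTCTCTATTAAGCG
CCAGCGAGGTGTTTGCCTCTGCATTTTTCAGCAAAGCAAGCTCCCTTTCCAGCTTGAATC
TATGTTCACGCTCATCCGACAATTCTTTTTCATACTTTCTTTGTGTACTCGTAAGCACTT
TTTTAAACTCACTTGTCATTATTGAAAGTGAACGTGATCCAGAACCGCTTGTGGGGCTTC
CTACAGAGGAAGGTGAACTTGGATCCCAAGTCACCGGCGAACTCGCTGGTGATGACATGC
CGAAATTATGTCTGCTTGAATTCAGCTTGTTGTTGGCTTTTTC
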
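>ADE2 YOR128C chrXV:564476-566191(-) plus 500bp flanks, ORF plus-oriented
TTTTGACCAGGTTATTATAAAAGAAACTTCATGCTCGAAAAAGATCATTTCGAAAAGTTG
CCTAGTTTCATGAAATTTTAAAGCAGTTTATATAAATTTTACCTTTTGATGCGGAATTGA
CTTTTTCTTGAATAATACATAACTTTTCTTAAAAGAATCAAAGACAGATAAAATTTAAGA
GATATTAAATATTAGTGAGAAGCCGAGAATTTTGTAACACCAACATAACACTGACATCTT
TAACAACTTTTAATTATGATACATTTCTTACGTCATGATTGATTATTACAGCTATGCTGA
CAAATGACTCTTGTTGCATGGCTACGAACCGGGTAATACTAAGTGATTGACTCTTGCTGA
CCTTTTATTAAGAACTAAATGGACAATATTATGGAGCATTTCATGTATAAATTGGTGCGT
AAAATCGTTGGATCTCTCTTCTAAGTACATCCTACTATAACAATCAAGAAAAACAAGAAA
ATCGGACAAAACAATCAAGTATGGATTCTAGAACAGTTGGTATATTAGGAGGGGGACAAT
TGGGACGTATGATTGTTGAGGCAGCAAACAGGCTCAACATTAAGACGGTAATACTAGATG
CTGAAAATTCTCCTGCCAAACAAATAAGCAACTCCAATGACCACGTTAATGGCTCCTTTT
CCAATCCTCTTGATATCGAAAAACTAGCTGAAAAATGTGATGTGCTAACGATTGAGATTG
AGCATGTTGATGTTCCTACACTAAAGAATCTTCAAGTAAAACATCCCAAATTAAAAATTT
ACCCTTCTCCAGAAACAATCAGATTGATACAAGACAAATATATTCAAAAAGAGCATTTAA
TCAAAAATGGTATAGCAGTTACCCAAAGTGTTCCTGTGGAACAAGCCAGTGAGACGTCCC
TATTGAATGTTGGAAGAGATTTGGGTTTTCCATTCGTCTTGAAGTCGAGGACTTTGGCAT
ACGATGGAAGAGGTAACTTCGTTGTAAAGAATAAGGAAATGATTCCGGAAGCTTTGGAAG
TACTGAAGGATCGTCCTTTGTACGCCGAAAAATGGGCACCATTTACTAAAGAATTAGCAG
TCATGATTGTGAGATCTGTTAACGGTTTAGTGTTTTCTTACCCAATTGTAGAGACTATCC
ACAAGGACAATATTTGTGACTTATGTTATGCGCCTGCTAGAGTTCCGGACTCCGTTCAAC
TTAAGGCGAAGTTGTTGGCAGAAAATGCAATCAAATCTTTTCCCGGTTGTGGTATATTTG
GTGTGGAAATGTTCTATTTAGAAACAGGGGAATTGCTTATTAACGAAATTGCCCCAAGGC
CTCACAACTCTGGACATTATACCATTGATGCTTGCGTCACTTCTCAATTTGAAGCTCATT
TGAGATCAATATTGGATTTGCCAATGCCAAAGAATTTCACATCTTTCTCCACCATTACAA
CGAACGCCATTATGCTAAATGTTCTTGGAGACAAACATACAAAAGATAAAGAGCTAGAAA
CTTGCGAAAGAGCATTGGCGACTCCAGGTTCCTCAGTGTACTTATATGGAAAAGAGTCTA
GACCTAACAGAAAAGTAGGTCACATAAATATTATTGCCTCCAGTATGGCGGAATGTGAAC
AAAGGCTGAACTACATTACAGGTAGAACTGATATTCCAATCAAAATCTCTGTCGCTCAAA
AGTTGGACTTGGAAGCAATGGTCAAACCATTGGTTGGAATCATCATGGGATCAGACTCTG
ACTTGCCGGTAATGTCTGCCGCATGTGCGGTTTTAAAAGATTTTGGCGTTCCATTTGAAG
TGACAATAGTCTCTGCTCATAGAACTCCACATAGGATGTCAGCATATGCTATTTCCGCAA
GCAAGCGTGGAATTAAAACAATTATCGCTGGAGCTGGTGGGGCTGCTCACTTGCCAGGTA
TGGTGGCTGCAATGACACCACTTCCTGTCATCGGTGTGCCCGTAAAAGGTTCTTGTCTAG
ATGGAGTAGATTCTTTACATTCAATTGTGCAAATGCCTAGAGGTGTTCCAGTAGCTACCG
TCGCTATTAATAATAGTACGAACGCTGCGCTGTTGGCTGTCAGACTGCTTGGCGCTTATG
ATTCAAGTTATACAACGAAAATGGAACAGTTTTTATTAAAGCAAGAAGAAGAAGTTCTTG
TCAAAGCACAAAAGTTAGAAACTGTCGGTTACGAAGCTTATCTAGAAAACAAGTAATATA
TAAGTTTATTGATATACTTGTACAGCAAATAATTATAAAATGATATACCTATTTTTTAGG
CTTTGTTATGATTACATCAAATGTGGACTTCATACATAGAAATCAACGCTTACAGGTGTC
CTTTTTTAAGAATTTCATACATAAGATCACTTATTATACATACATACATATCCAGTAACA
AGAAGCAAGGAATAATTACCTGCTTAAGTCTGCGATTAAAAAAATAACGTTTCGATACAG
TTCATATAAGGCGGCTCAATGCAGAACCGAGGATAGCGCTACGTCAGGATATCTTTGTAG
TTCCCAAATATAAATGCGACAATATAGTTTCTTTCTTTCATATCAATAATATCCTTTTCT
CCACTGAAATCACGAATCAAACCTGGAGCAAAAACTAAAGCCAAATTATAAAGCGTCATT
CGATTCCAGTGACTGTACCGTGTAACCTTTTCTATATGTTCACTCAGTACTCTTAACACC
CTATAATGTTCCCTTG
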
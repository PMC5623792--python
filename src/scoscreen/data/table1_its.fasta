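>Candida_inconspicua_IG_11 LC164191.1 partial ITS region, 326 bp
CAAAAAACAAAACTTTCAACAACGGATCTCTTGGTTCTCGCATCGATGAAGAGCGCAGCG
AAATGCGATACCTAGTGTGAATTGCAGCCATCGTGAATCATCGAGTTCTTGAACGCACAT
TGCGCCCTCTGGTATTCCGGAGGGCATGCCTGTTTGAGCGTCGTTTCCTTCTTGCTTGCG
AGCAGAAATGGGGGGGCCCTGGCATTGGGGCCGCTCTGAAAAGAAACGTTGCGGGCGAAG
CGAACTATGAGTAGGACGCTTGGCCGCCGAACTTAATACATAAGCTCGACCTCAAATCAG
GTAGGAATACCCGCTGAACTTAAGCA
>Debaryomyces_hansenii_1 LC126697.1 partial ITS region, 394 bp
ACTTTTGCTTTGGTCTGGACTAGAAATAGTTTGGGCCAGAGGTTTACTGAACTAAACTTC
AATATTTATATTGAATTGTTATTTATTTAATTGTCAATTTGTTGATTAAATTCAAAAAAT
CTTCAAAACTTTCAACAACGGATCTCTTGGTTCTCGCATCGATGAAGAACGCAGCGAAAT
GCGATAAGTAATATGAATTGCAGATTTTCGTGAATCATCGAATCTTTGAACGCACATTGC
GCCCTCTGGTATTCCAGAGGGCATGCCTGTTTGAGCGTCATTTCTCTCTCAAACCTTCGG
GTTTGGTATTGAGTGATACTCTTAGTTGAACTAGGCGTTTGCTTGAAATGTATTGGCATG
AGTGGTACTGGATAGTGCTATATGACTTTCAATG
>Debaryomyces_hansenii_IG_01 LC164190.1 partial ITS region, 443 bp
GAACTTTTGCTTTGGTCTGGACTAGAAATAGTTTGGGCCAGAGGTTTACTGAACTAAACT
TCAATATTTATATTGAATTGTTATTTATTTAATTGTCAATTTGTTGATTAAATTCAAAAA
ATCTTCAAAACTTTCAACAACGGATCTCTTGGTTCTCGCATCGATGAAGAACGCAGCGAA
ATGCGATAAGTAATATGAATTGCAGATTTTCGTGAATCATCGAATCTTTGAACGCACATT
GCGCCCTCTGGTATTCCAGAGGGCATGCCTGTTTGAGCGTCATTTCTCTCTCAAACCTTC
GGGTTTGGTATTGAGTGATACTCTTAGTTGAACTAGGCGTTTGCTTGAAATGTATTGGCA
TGAGTGGTACTGGATAGTGCTATATGACTTTCAATGTATTAGGTTTATCCAACTCGTTGA
ATAGTTTAATGGTATATTTCTCG
>Debaryomyces_hansenii_IG_II LC164187.1 partial ITS region, 426 bp
CTTTTGCTTTGGTCTGGACTAGAAATAGTTTGGGCCAGAGGTTTACTGAACTAAACTTCA
ATATTTATATTGAATTGTTATTTATTTAATTGTCAATTTGTTGATTAAATTCAAAAAATC
TTCAAAACTTTCAACAACGGATCTCTTGGTTCTCGCATCGATGAAGAACGCAGCGAAATG
CGATAAGTAATATGAATTGCAGATTTTCGTGAATCATCGAATCTTTGAACGCACATTGCG
CCCTCTGGTATTCCAGAGGGCATGCCTGTTTGAGCGTCATTTCTCTCTCAAACCTTCGGG
TTTGGTATTGAGTGATACTCTTAGTTGAACTAGGCGTTTGCTTGAAATGTATTGGCATGA
GTGGTACTGGATAGTGCTATATGACTTTCAATGTATTAGGTTTATCCAACTCGTTGAATA
GTTTAA
>Kazachstania_unispora_IG_16 LC164188.1 partial ITS region, 338 bp
GCCGAACCAGCGCTTAATTGCGCGGTTTGGTGGGTCTCTGTAGCTCAGTAGCACTATTAC
ACACTGTGGAGATTTTATAATTCTTTGCATGCTTCTTTGGGCAGCTTCGGCAGCCCAGAG
GTAACAAACACAAACAACTTTGTAATATTTTTAACCCAGTCAAAACCAGAATTCCAGAAA
GATTTATCTTTTTGTAATATTATAACAAATATTCAAAACTTTCAACAACGGATCTCTTGG
TTCTCGCATCGATGAAGAACGCAGCGAAATGCGATACGTAATGTGAATTGCAGAATTCCG
TGAATCATCGAATCTTTGAACGCACATTGCGCCCCTTG
>Kluyveromyces_marxianus_IG_1 LC126698.1 partial ITS region, 401 bp
TTCTCATCCTAAACACAATGGAGTTTTTTCTCTATGAACTACTTCCCTGGAGAGCTCGTC
TCTCCAGTGGACATAAACACAAACAATATTTTGTATTATGAAAAACTATTATACTATAAA
ATTTAATATTCAAAACTTTCAACAACGGATCTCTTGGTTCTCGCATCGATGAAGAACGCA
GCGAATTGCGATATGTATTGTGAATTGCAGATTTTCGTGAATCATCAAATCTTTGAACGC
ACATTGCGCCCTCTGGTATTCCAGGGGGCATGCCTGTTTGAGCGTCATTTCTCTCTCAAA
CCTTTGGGTTTGGTAGTGAGTGATACTCGTCTCGGGTTAACTTGAAAGTGGCTAGCCGTT
GCCATCTGCGTGAGCAGGGCTGCGTGTCAAGTCTATGGACT
>Zygotorulaspora_florentina_IG_12 partial ITS region, 484 bp
CTGACACATACACACAGTGGAGATATATTCTTTCTTCTTCTTCTTCTTTGGGGGACGGCG
GTTTGCGCTGCTGCTCCCAGAATGAAAAAACACAAACAACTTTTGTATTATTACAGATGT
CAAAACACAAAACAAAATACCAAAACTTTCAACAACGGATCTCTTGGTTCTCGCATCGAT
GAAGAACGCAGCGAAATGCGATACGTAATGTGAATTGCAGAATTCCGTGAATCATCGAAT
CTTTGAACGCACATTGCGCCCCTTGGTATTCCAGGGGGCATGCCTGTTTGAGCGTCATTT
CCTTCTCAAACACTTGTGTTTGGTAGTGAGTGATACTCTGTAACATGGGAGTTAGCTTGA
AATTGAGAGCCCATGGGCTGCTCTGCTGAGGCGGAAGTCGTGCTAGGTAACACCAACTCG
ACGCAACGCATTCGGCTGGACGCAGCTCCGGCGAACAAACACATCAACGCTTGACCTCAA
ATCA
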
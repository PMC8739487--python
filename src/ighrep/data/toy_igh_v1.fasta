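>TOYV1 segment=V cdr3_anchor=288 fr1_end=75
ACCGTTGCTCGGCGGTCGACCGGGATAACCGAATTGGTAGTGGGTGTTCTTACTTCCCGTCTGCCGAGTTGTGTTGCTCGATCAGACCGTCGTATCACCGACTGCAATTCGTCACAAGCGAGGGTGGGGCCCACATTGCGTTGCGGCGTTGTGAGTCCGCTACTGAAGGACAGCGTCGGCTGTGTCCCGTTGCGCCATTGGCCGACACTATACAGTCTAACTGGCCTCCCAATCGAGGGATTACGGAGCTCAGCGGGGACCCATGTGTCACGGTATTCCCCTTGCCACTGT
>TOYV2 segment=V cdr3_anchor=288 fr1_end=75
ATGGGCGCGAGATCAATATATAAATACTACGTTGGACTAGGTCAAGTTGACCGTCTGGAGAAGAGAATGACGCGGGGAGCTCTATCGGAGACAGTGGATGCGGAGGACACCGAGTACCAGGCAAACCCCCGGTTGATCCAACGATTTTCGAAGATGTCAAATTCGCACTGGCACCGGGGAACTGACCTGGTTTTTGGACGACGACGCTATCATAGGCCAAACACGACCGTTGTAGGGCTAGGTAGCTGCCTGTTAAGCCTGGGGCTGCGTAGGCCTATGCAGGGCGCGTGT
>TOYV3 segment=V cdr3_anchor=288 fr1_end=75
GCCCCGTTCACCCCAACTCCATTCCCGTGGCTGGGGCGTCAAGTGTTGCAAGTTATTGGTTACCGTGTACAAACAACCCGTTGGACTCGTGGGATAGTACAGTATGATGACAGGCTATCGAACGTGCTGGGTGGACGGCAGGCGAGAGATACCGCTGCGACCGTGCGCTACAAGAGGCTGAGTCCAGGAAGAGGCACGAGGGATTACAGGCAGTGTTTTGATCGTCCCGCCGCACACAACAGCTTCCGCCTCCTAGTTAATACCCAACTCGGACTCCGGTTAAGCGAGTGT
>TOYV4 segment=V cdr3_anchor=288 fr1_end=75
GACCTATATCAATTCCCAGACCTTTCCCGGCACAACCCGTCAAAATGCGACAGACAGGACCATACGGGAGGCACTCACATGGGAGTAGTATTAGTGCATACGGCCTGGTTGATGATGAAGAGAGACGACCCGCAGTCACTATATTTCCATATATTCGCGCACGCCCTTTGGATTTTTTTAAGTAGGGAAAAGCAGCGGTTGTTTAGCTGCACCGTCTCCTGCATCTGCACTCTTCTACATAACGTTCCAGGACGCCCGTGCACCGTAGTCCCTCAAAAATTATTAATGTGT
>TOYV5 segment=V cdr3_anchor=288 fr1_end=75
AACACTACATCATGCAGCGTCAGGCCGGCAGGTTCTAAGAGTCACCAGTTTGTTCATTTGCTGCTGCGGAGATGTAAAAGGATGCACAGAAACGGCTTGACTCAGCTGTGTGGGGTGGATCGCATATCGTATAACGGTACCGTCTCAACTCGGACTGAGTGTACACGATTGCAGAGACTCCTTGGACATTTCCTTCACTTCTGTCTGAACGCAGACAGCGCGTCCACGGTAAGAGTCCGCAAATTCAGGGCAAGTTGTGTCTATCGGCTAGCGGTTTCCAACGGAACGTGT
>TOYV6 segment=V cdr3_anchor=288 fr1_end=75
CACTCAATTTACCTAATGCCAGAAGTGGCATGTTCGGTCGCACACCGCACTCCGTGTCGCACGGCTTTCTCGCAACGTGAAATTCAAATGTTTGTCTCCTATTTCACGTCTACACTCGCACCCAGAAGTTCACATCAGTGTAGATGGTGTGCAAGGAGCCACGATAGCCGTACTGAAAACGGTAATAGTAGGTCAAATCGGGCACTTGGCTACCGATCACATTTTCTGGTATCTTACTCCGAAAAGCTGAGTTGCATGATCATTGCTGAGTTACGCCACAATAAACCGTGT
>TOYV7 segment=V cdr3_anchor=288 fr1_end=75
TGTCTTTGCACGACCTCAACGAATCGATGTGGGACGTCCTCCTACTGGATGTTGCATTACGATGTTGCGGCTGCCGTTGTCAGATCAGAACATCTTTTCTCGTCACTAGTTCCTGGCGCTATTCAAAATAGACGGCTCAGGCGCGCAATGCCACCGCTGCCGGTACATCGGCCTAGTGGCATGCAGTACTTAGGATGGTCGCTCGTGCCACTAGAATTCTCCCTCGCTATATATGACGAAGTGGCGACACACAGGGTAAAGATAGCAGGGCTGTCGTGTAGATTCGCCTGT
>TOYV8 segment=V cdr3_anchor=288 fr1_end=75
GCGACCGCCGTAGATACCCTTTTAGTAAGATTCTTCAGGTACCGAGCACGTGTTTTTTACTGTTTAACCATTGTAGATAATACCCTTGCCAGGAGGACTGAGAAAGAGCTCCTAGGCCTTGTAGTGTGTTACCTTCTGATGGCAAGATGTTCCACTGTTACTGGTACCCTCGGAGTACGCTGTGTTATAGGAGTACCAGTCTGCTATGTGGCGCAATACCCGGAACATCATAGCTTCAGCACCTTAGACCGGGTACCTACTGTAAGGGACTTATTACCGGTTGCCCTCTGT
>TOYJ1 segment=J cdr3_anchor=0
TGGAGACCGGCTTTTAAAGGTTCCTTCCGCACTCAATCCTCTGCGACT
>TOYJ2 segment=J cdr3_anchor=0
TGGACTCTCGATAACGGCGACAAAACCCGTGTATCACGGCAGTTGCGT
>TOYJ3 segment=J cdr3_anchor=0
TGGCATCGGAAACAGCTTTGTGTCGTTGACACGCCTTTTAAGTCTGGC
>TOYJ4 segment=J cdr3_anchor=0
TGGCACGTTTCCAAGACGGGATTTAACGGAAGAGCTGCGACCGGCTGC
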
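>IGHV1-S*01 synthetic V segment (randomly generated, not a real germline)
CGACTTGCGTGCTTAGCCGTCATAAGCTGGCCCGAGCTATGGCGCAGGCGTCTACAACCGGTTCACGCTGTCTCAACTTCCACGCGAAAGAGATTGACTTCGGGCGGCCTAGACGGACCGGACACATCTTTAAGAAACTCTTTCACGAACCGTCCGCGACGTAACAGCCGTCCCCGCGCATATAACTTGATCAATTTGTCGCAACAAAAGCTCATAAGGTTCGGCCGTGGCTGGGCTCACCTGTGGTCTATCTGTAGGTCGACCCGTGTCCATGCCTGCACATCATCCATAAGGATTCTTTCAGTAAGG
>IGHV2-S*01 synthetic V segment (randomly generated, not a real germline)
ACCCGTACGCTAATGCGTGTGGTTGACACATGTTGCCTGAGGGCCCACAACATGTTCATGATCGTCTTATTCGATGTCAAAAGCCAACCCACCTACAAACACCCTGGGTACGTCACGCAGTTATCAATACCTCAGAAATGCTTGGATATACACGGAATCGAAAGTGGACCGCAAGGCGGTCCTTCCGTCTCGATTAGCACCGATGTCAATACTTACGTGAGGGGATTTCATGATAGCTCTTTCGCAGAAAGGTTTAGTATCCTTTATCCAAGCTGTGAGATGAGACCCTCGCCGAAAGACGGCGCCCTT
>IGHV3-S*01 synthetic V segment (randomly generated, not a real germline)
GCACAGCCAGCAAATCTACACGGCAGGACCCGCGTTAAAGTCACCAGGCGAGGCATCTCCAGAAGGCGATCGGTGCCCCCTTGTACACGCGGACTGTGCCTCGACTACCTCACACAGAACCTGCCAGCGCATGCGGGGGGCATTCCACCTAACCAGCCGTTAGACGTCAGTACTGGCGTTTCTTGCTTGAACAGCTCGTGTCCGTCGGATGGGAGGCTTCCCGCTGCACCCTGCGGACTCAGATGGTTAGACGGACAGCAGCATGATAGCGTATCACTCCTACCACTTTCTTGTATTCGATCGCAATCC
>IGHV4-S*01 synthetic V segment (randomly generated, not a real germline)
AATGGGAAATTATTGCACTTCAACGCGCAGATCGACCGCATAACCCACCATAACAAGGTTACCCGTCGTTGCGACTTGACCGAATATCTATCTATCGATTGTATCATTTCTGATACGGCGAATTTTCCCTTTCCACCGAACGAGCATTCGAATCTCCTGGCTGGGCACAGCTCTCCTCGACCGTCTCCGCTACCACTTCGTAATGCAATGCACCACCCTCGGTCTCTCAAATCCGAGTATGCCTCGGATCGTAGTTCGCATGAATCAGGATTTCCGTCAACTCGTTGCTGCCTTTTGAAAAAGATCTTA
>IGHV5-S*01 synthetic V segment (randomly generated, not a real germline)
ACGACCGCAGCAGACAGTCCTCCTGTGAAGTTAAGGGCTCGGTTGCTGACACGTGATACAGAAATTGTCCTTGCTACCTGGAAGCTGTGCAACGGCTTAGTCCGCATAGAACAAGACACTGCGATAGCTTGCCAGCTCTCGCACAAGGACCAGCCGGCGGCTGCGGAAGCGCCGTTTATGATTTCCATGTGCGTTGCGACATCCAGCGCACCTAGGGCATTGCGACAGCGGTTGTTCCCGGGCTTATTAACAAGCACTAAAGTCACCATCTTTGCGGACTCAGCTCACCCTATGATTGCCACCCCCTTT
>IGHV6-S*01 synthetic V segment (randomly generated, not a real germline)
GAAGTTCCGCAACCTGCATGCGTGAAGTGCTCAGTCGAGTTTTCCGATTTAAATGCGCTTAATGGTCGTAAATGTCCTGGTGGAGAGTGGTTCGGTGGTAGAGTGACTATGAATCTGAGTCGGACACCACTCCCGTGGTCCTATGGACTACCTGAAGGACCTGTCCGCGTAAAGCGACTGCGTAGTACTTTCACAAAACGTTCAAGGATTAACTGCTCCAAGACATATGCTCCTCGTAGATGCCCAAGTAACCTCATCTTACACGGTTTCAAGAGGTCTTTCAGATGCCTAGACTATTTGGCCCTTGGA
>IGHJ1-S*01 synthetic J segment (randomly generated, not a real germline)
CAGCTGGCCGCGACATGGTATCTCTCGGATCTATGTTTTTCTGACGTG
>IGHJ2-S*01 synthetic J segment (randomly generated, not a real germline)
AAACTGGACAGCTCGATGACCGATGCCTCAGAGTTAAATCCAGCCTGG
>IGHJ3-S*01 synthetic J segment (randomly generated, not a real germline)
TGTATGGATACAGACCATAGTACGAACGGGTCTCTGATGACGCCTCGG
>IGHJ4-S*01 synthetic J segment (randomly generated, not a real germline)
GGTTTCTCCTCAGCGCCCTTAGGCACTAAGAAAGAAAGAGGTTGTTTG
>IGHJ5-S*01 synthetic J segment (randomly generated, not a real germline)
CGCAGTAGGTTATTCATTGCGACTCCCCTGCTAGGGAGATGGACTTTC
>IGHJ6-S*01 synthetic J segment (randomly generated, not a real germline)
GCGTCGCTCACTTTTCACCTTAGAAAACAATTTAGGATGCAAGACGAT
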
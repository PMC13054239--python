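>taxon|synthetic COI-5P profile|group=earthworm
TTTATTATGTGTTTCCATGACAATTGCATTCCCATATTTATTGGGGTACTACGTGAGAGATCGTAGACTC
TCGCGCTATGTACTCTACTCCCGCGACTCCTTAATCCCATTAAGTGGAGGTAACAGTCCTCCCAACGTAG
GCCGATCGGCTGGGGTCATTCCGCTCCACCTTTACCACTGAACTGGTAAGAAAGCATGCAAGTTTCACCT
ACTCTGGCGTTTTTGATACGGAGGCCGTCTTGCCTGCTCCGTGACGTACGCCCTAATGAGCCATATCCAT
GACTGAGGGCTCCTACTGGTCGCCTATTGGCTGCTCTGGTTACCGGCTGCGGAAGTTTCCCTGTGTTTGG
TTCGACACGCGTTTACTATTGCGTGCCCTCGCCGTACCCCCTCTAGGCGAGAGGATAAATGACATAGCGA
GCAGTTGGTTTTACAGTTTTACCAACCTAGTTCAACAGTTTATTACGGAATGATGAGCGGCGGGAGTTGG
AGGTGGCAACCGACACCTTCTCGTGAATCCTACAGGTGAAACTATGACTCACTTTTTGTAATGTGGAGAA
TAGAACTCACAACACGCCACGGCAATCTCGGTGACAGCGGTACGTTGGCCCTCCTAGACGACTGCAGTTG
TAACAGGGCGGCCTACTCCTTGCGGATT
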
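>short_96bp transposon-end gel-shift fragment (XmaI digest)
CCGGGCTGCAGGAATTCTATTAGGTTGGTGCAAAAGTAATTGCGGTTTTGGATCCCAAGC
TTCTTCTAGAGGTACCGCATGCGATATCGAGCTCTC
>long_162bp transposon-end gel-shift fragment (SacII/AccI digest)
GCGGTGGCGGCCGCTCTAGAACTAGTGGATCCCCCGGGCTGCAGGAATTCTATTAGGTTG
GTGCAAAAGTAATTGCGGTTTTGGATCCCAAGCTTCTTCTAGAGGTACCGCATGCGATAT
CGAGCTCTCCCGGGAATTCGATATCAAGCTTATCGATACCGT
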
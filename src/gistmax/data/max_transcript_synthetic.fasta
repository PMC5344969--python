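>MAX_transcript_synthetic length=603 cds=61..543 note=synthetic stand-in sequence, not the genuine NM_002382 mRNA
TCCACAGGAATTAATCGCCTTTTGTCCTGCAGCTCGCCTCAAAATCTAGGCCGTCGAGCG
ATGGCCCGGATAAACATCTCAGGGGGGAGAGGTTTTAGGCCAGAAGACTATTGGAATTTC
CCTGACGGCGTGGTCCCCGTAAGGTACAGAAGCATTGGCATATCAAACACGAAACGTCTA
CAACGGAATATCAGAAATGGTCTCGCCCGATTAGATGTTGTATCGAAAATAAAGGGCTAT
TCAGTAGTGGCACGATCTTGTGCCGAGCCAGACCTCGAATTGATAGTGCATGTCTCTAAT
AAAACATGGGGTCGGCCTAAACTGGAACTATGGCGAGTGCCTTGCTACTGCGGCTCTGGC
GGTTACCACCATACGGCAAAATTTTTCCCTCTAATCCATATTGAGGCACGTTTTGCCTGC
CCAGAGAGCTTCCATCCTCGGGAAGGGTGGCGTTACGCGACAGTACGACCCAGGACTAAT
TACTCGAGGCTGGCTGCCAGCCTTCCCTGTGGTCCGTTCATAATTGTAGACATCACCTAT
TAACACGTTTGTAAGAGAACCCGTGACTCGTCGGGTCCCGGTACTGACCCGTTCCCATAT
GGT
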
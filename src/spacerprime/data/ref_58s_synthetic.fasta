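>r58S_consensus_synthetic synthetic 153 bp clitellate-style 5.8S reference; 606F/CM1 site at 10..30, CM2 at 60, CM3 at 100; GC 0.556; contains no CATTA
AGGTTAGATGGTCGATGAAGAGCGCAGCCATGGGCCTAGATACCGCCGTTATTTGCGGAAGAATTGCAGA
ACTCTCCCCCCTGCGGTACTCAGCATTCTGTTTGAACGCAGGCAACCTGCAGGGGCAATTCGCATCCCAG
CAGGTCGGTCGTT
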
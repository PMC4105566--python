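>oligo_dT_modified broken-poly-T cDNA synthesis primer (terminal degenerate base omitted)
AAGCAGTGGTATCAACGCAGAGTCGCAGTCGGTACTTTTTTCTTTTTT
>gs454_adaptor_A
GCCTCCCTCGCGCCATCAG
>gs454_adaptor_B
GCCTTGCCAGCCCGCTCAG
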
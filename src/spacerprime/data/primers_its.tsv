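name	seq	orientation
29F	AAAGTCGTAACAAGGTTTCCGTA	forward
1084R	YGTTAGTTTCTTTTCCTCCGCTT	reverse
606F	GTCGATGAAGAGCGCAGCCA	forward
1082R	TTAGTTTCTTTTCCTCCGCTT	reverse
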
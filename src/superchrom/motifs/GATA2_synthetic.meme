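MEME version 4

ALPHABET= ACGT

strands: + -

Background letter frequencies
A 0.25000 C 0.25000 G 0.25000 T 0.25000

MOTIF GATA2_synthetic
letter-probability matrix: alength= 4 w= 8 nsites= 20 E= 0
0.400000 0.200000 0.200000 0.200000
0.475000 0.025000 0.025000 0.475000
0.020000 0.020000 0.940000 0.020000
0.940000 0.020000 0.020000 0.020000
0.020000 0.020000 0.020000 0.940000
0.940000 0.020000 0.020000 0.020000
0.940000 0.020000 0.020000 0.020000
0.475000 0.025000 0.475000 0.025000
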
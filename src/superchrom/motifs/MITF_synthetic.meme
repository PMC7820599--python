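MEME version 4

ALPHABET= ACGT

strands: + -

Background letter frequencies
A 0.25000 C 0.25000 G 0.25000 T 0.25000

MOTIF MITF_synthetic
letter-probability matrix: alength= 4 w= 8 nsites= 20 E= 0
0.100000 0.100000 0.100000 0.700000
0.040000 0.880000 0.040000 0.040000
0.880000 0.040000 0.040000 0.040000
0.020000 0.940000 0.020000 0.020000
0.020000 0.020000 0.940000 0.020000
0.040000 0.040000 0.040000 0.880000
0.040000 0.040000 0.880000 0.040000
0.700000 0.100000 0.100000 0.100000
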
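#name=deformability
#unit=arbitrary (protein-induced deformability)
#source=Olson WK et al. (1998) PNAS 95:11163-11168; dinucleotide deformability from protein-DNA crystal structures
AA	2.9
AC	2.3
AG	2.1
AT	1.6
CA	9.8
CC	6.1
CG	12.1
CT	2.1
GA	4.5
GC	4.0
GG	6.1
GT	2.3
TA	6.3
TC	4.5
TG	9.8
TT	2.9
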
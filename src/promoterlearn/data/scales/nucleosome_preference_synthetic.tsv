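#name=nucleosome_preference
#unit=arbitrary (relative preference)
#source=SYNTHETIC stand-in: rule-based trinucleotide preferences (GC-rich favored, A/T-only triplets disfavored), reverse-complement symmetric; not a transcription of a published table
AAA	-0.4
AAC	0.15
AAG	0.15
AAT	-0.4
ACA	0.15
ACC	0.3
ACG	0.3
ACT	0.15
AGA	0.15
AGC	0.3
AGG	0.3
AGT	0.15
ATA	-0.4
ATC	0.15
ATG	0.15
ATT	-0.4
CAA	0.15
CAC	0.3
CAG	0.3
CAT	0.15
CCA	0.3
CCC	0.45
CCG	0.45
CCT	0.3
CGA	0.3
CGC	0.45
CGG	0.45
CGT	0.3
CTA	0.15
CTC	0.3
CTG	0.3
CTT	0.15
GAA	0.15
GAC	0.3
GAG	0.3
GAT	0.15
GCA	0.3
GCC	0.45
GCG	0.45
GCT	0.3
GGA	0.3
GGC	0.45
GGG	0.45
GGT	0.3
GTA	0.15
GTC	0.3
GTG	0.3
GTT	0.15
TAA	-0.4
TAC	0.15
TAG	0.15
TAT	-0.4
TCA	0.15
TCC	0.3
TCG	0.3
TCT	0.15
TGA	0.15
TGC	0.3
TGG	0.3
TGT	0.15
TTA	-0.4
TTC	0.15
TTG	0.15
TTT	-0.4
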
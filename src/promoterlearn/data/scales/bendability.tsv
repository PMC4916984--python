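#name=bendability
#unit=arbitrary (bend propensity)
#source=Brukner I et al. (1995) EMBO J 14:1812-1818; trinucleotide DNase I / nucleosome bend propensities, symmetric expansion to 64 words
AAA	-0.274
AAC	-0.205
AAG	-0.081
AAT	-0.28
ACA	-0.006
ACC	-0.032
ACG	-0.033
ACT	-0.183
AGA	0.027
AGC	0.017
AGG	-0.057
AGT	-0.183
ATA	0.182
ATC	-0.11
ATG	0.134
ATT	-0.28
CAA	0.015
CAC	0.04
CAG	0.175
CAT	0.134
CCA	-0.246
CCC	-0.012
CCG	-0.136
CCT	-0.057
CGA	-0.003
CGC	-0.077
CGG	-0.136
CGT	-0.033
CTA	0.09
CTC	0.031
CTG	0.175
CTT	-0.081
GAA	-0.037
GAC	-0.013
GAG	0.031
GAT	-0.11
GCA	0.076
GCC	0.107
GCG	-0.077
GCT	0.017
GGA	0.013
GGC	0.107
GGG	-0.012
GGT	-0.032
GTA	0.025
GTC	-0.013
GTG	0.04
GTT	-0.205
TAA	0.068
TAC	0.025
TAG	0.09
TAT	0.182
TCA	0.194
TCC	0.013
TCG	-0.003
TCT	0.027
TGA	0.194
TGC	0.076
TGG	-0.246
TGT	-0.006
TTA	0.068
TTC	-0.037
TTG	0.015
TTT	-0.274
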
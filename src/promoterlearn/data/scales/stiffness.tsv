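#name=stiffness
#unit=nm (bending persistence length)
#source=per-dinucleotide bending stiffness after Geggier & Vologodskii (2010) PNAS 107:15421-15426; approximate transcription, verify against the original before scientific use
AA	50.4
AC	44.7
AG	54.4
AT	40.9
CA	46.7
CC	41.7
CG	56.0
CT	54.4
GA	51.2
GC	44.1
GG	41.7
GT	44.7
TA	42.0
TC	51.2
TG	46.7
TT	50.4
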
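# Synthetic illustrative optimal-codon table: one commonly preferred
# codon per degenerate amino-acid family. Ships as a runnable default;
# supply a cohort-appropriate table for real analyses.
codon	optimal
AAA	0
AAC	1
AAG	1
AAT	0
ACA	0
ACC	1
ACG	0
ACT	0
AGA	0
AGC	1
AGG	0
AGT	0
ATA	0
ATC	1
ATG	0
ATT	0
CAA	0
CAC	1
CAG	1
CAT	0
CCA	0
CCC	1
CCG	0
CCT	0
CGA	0
CGC	1
CGG	0
CGT	0
CTA	0
CTC	0
CTG	1
CTT	0
GAA	0
GAC	1
GAG	1
GAT	0
GCA	0
GCC	1
GCG	0
GCT	0
GGA	0
GGC	1
GGG	0
GGT	0
GTA	0
GTC	0
GTG	1
GTT	0
TAC	1
TAT	0
TCA	0
TCC	0
TCG	0
TCT	0
TGC	1
TGG	0
TGT	0
TTA	0
TTC	1
TTG	0
TTT	0
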
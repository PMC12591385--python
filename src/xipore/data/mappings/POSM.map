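# palmitoyl sphingomyelin (newly authored), 12-bead mapping with the sphingosine 4,5-trans double bond
[residue] POSM
[beads]
NC3: N C12 C13 C14 C15 C11
PO4: P O11 O12 O13 O14
AM1: C2S H2S NF C1F OF
AM2: C1S C3S H3S O3S
T1A: C4S C5S C6S C7S
C2A: C8S C9S C10S C11S
C3A: C12S C13S C14S C15S
C4A: C16S C17S C18S
C1B: CB2 CB3 CB4 CB5
C2B: CB6 CB7 CB8 CB9
C3B: CB10 CB11 CB12 CB13
C4B: CB14 CB15 CB16
[bonds]
N C12
N C13
N C14
N C15
C12 C11
C11 O12
P O11
P O12
P O13
P O14
O11 C1S
C1S C2S
C2S H2S
C2S NF
NF C1F
C1F OF 0.123
C1F CB2
C2S C3S
C3S H3S
C3S O3S
C4S C5S 0.134
C5S C6S
C6S C7S
C7S C8S
C8S C9S
C9S C10S
C10S C11S
C11S C12S
C12S C13S
C13S C14S
C14S C15S
C15S C16S
C16S C17S
C17S C18S
C3S C4S
CB2 CB3
CB3 CB4
CB4 CB5
CB5 CB6
CB6 CB7
CB7 CB8
CB8 CB9
CB9 CB10
CB10 CB11
CB11 CB12
CB12 CB13
CB13 CB14
CB14 CB15
CB15 CB16
[chiral]
C2S C1S NF H2S -1
C3S C2S C4S H3S -1
[cis]
[trans]
C3S C4S C5S C6S
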
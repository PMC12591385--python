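# palmitoyl-oleoyl phosphatidylserine, 12-bead mapping
[residue] POPS
[beads]
CNO: C11 C12 H12 N C13 O15 O16
PO4: P O11 O12 O13 O14
GL1: C1 C2 H2 O21 C21 O22
GL2: C3 O31 C31 O32
C1A: CA2 CA3 CA4 CA5
D2A: CA6 CA7 CA8 CA9 CA10
C3A: CA11 CA12 CA13 CA14
C4A: CA15 CA16 CA17 CA18
C1B: CB2 CB3 CB4 CB5
C2B: CB6 CB7 CB8 CB9
C3B: CB10 CB11 CB12 CB13
C4B: CB14 CB15 CB16
[bonds]
C12 H12
C12 N
C12 C13
C13 O15 0.123
C13 O16
O12 C11
C11 C12
P O11
P O12
P O13
P O14
O11 C1
C1 C2
C2 H2
C2 O21
O21 C21
C21 O22 0.123
C21 CA2
C2 C3
C3 O31
O31 C31
C31 O32 0.123
C31 CB2
CA2 CA3
CA3 CA4
CA4 CA5
CA5 CA6
CA6 CA7
CA7 CA8
CA8 CA9
CA9 CA10 0.134
CA10 CA11
CA11 CA12
CA12 CA13
CA13 CA14
CA14 CA15
CA15 CA16
CA16 CA17
CA17 CA18
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
C2 C1 C3 H2 +1
C12 C11 C13 H12 +1
[cis]
CA8 CA9 CA10 CA11
[trans]
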
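# cholesterol, 8-bead MARTINI-style mapping with all 8 chiral centers
[residue] CHOL
[beads]
ROH: O3 C3 H3
R1: C1 C2 C19
R2: C4 C5 C6
R3: C7 C8 H8
R4: C9 H9 C10 C11
R5: C12 C13 C18 C14 H14
C1: C15 C16 C17 H17 C20 H20 C21
C2: C22 C23 C24 C25 C26 C27
[bonds]
C1 C2
C2 C3
C3 C4
C4 C5
C5 C6 0.134
C6 C7
C7 C8
C8 C9
C9 C10
C10 C1
C5 C10
C9 C11
C11 C12
C12 C13
C13 C14
C14 C8
C14 C15
C15 C16
C16 C17
C17 C13
C10 C19
C13 C18
C17 C20
C20 C21
C20 C22
C22 C23
C23 C24
C24 C25
C25 C26
C25 C27
C3 O3
C3 H3
C8 H8
C9 H9
C14 H14
C17 H17
C20 H20
[chiral]
C3 C2 C4 H3 +1
C8 C7 C9 H8 -1
C9 C8 C11 H9 -1
C10 C1 C5 C19 +1
C13 C12 C14 C18 +1
C14 C8 C15 H14 -1
C17 C13 C16 H17 -1
C20 C17 C22 H20 +1
[cis]
[trans]
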
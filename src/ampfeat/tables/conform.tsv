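# Conformational-similarity reduction: 7 groups of residues with similar
# main-chain/side-chain conformational preferences (phi/psi behaviour):
# long polar/charged helix-compatible residues; cysteine; the short
# side-chain amides/acids D/N; bulky hydrophobics and aromatics; glycine
# and proline as conformational outliers; the small hydroxyl pair S/T.
# amino_acid	group_label
A	C_1
E	C_1
K	C_1
Q	C_1
R	C_1
C	C_2
D	C_3
N	C_3
F	C_4
H	C_4
I	C_4
L	C_4
M	C_4
V	C_4
W	C_4
Y	C_4
G	C_5
P	C_6
S	C_7
T	C_7
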
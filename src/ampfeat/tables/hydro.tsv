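# Hydropathy reduction: 5 groups from equal-width bins of the normalized
# Kyte-Doolittle hydropathy score, (KD + 4.5) / 9.0, bins [0,0.2) .. [0.8,1.0].
# H_1 = most hydrophilic, H_5 = most hydrophobic.
# amino_acid	group_label
R	H_1
K	H_1
N	H_1
D	H_1
Q	H_1
E	H_1
H	H_1
P	H_2
Y	H_2
W	H_3
S	H_3
T	H_3
G	H_3
A	H_4
M	H_4
C	H_4
F	H_5
L	H_5
V	H_5
I	H_5
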
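residue_type	delta_rc_ppm
A	52.5
C	58.2
D	54.2
E	56.6
F	57.7
G	45.1
H	55.0
I	61.1
K	56.2
L	55.1
M	55.4
N	53.1
P	63.3
Q	55.7
R	56.0
S	58.3
T	61.8
V	62.2
W	57.5
Y	57.9
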
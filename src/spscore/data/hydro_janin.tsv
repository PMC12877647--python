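# Janin buried/accessible free-energy transfer scale
residue	value
A	0.3
R	-1.4
N	-0.5
D	-0.6
C	0.9
Q	-0.7
E	-0.7
G	0.3
H	-0.1
I	0.7
L	0.5
K	-1.8
M	0.4
F	0.5
P	-0.3
S	-0.1
T	-0.2
W	0.3
Y	-0.4
V	0.6
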
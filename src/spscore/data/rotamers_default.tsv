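# Minimal backbone-independent side-chain rotamer library.
# Chi-angle modes at the canonical gauche-/trans/gauche+ wells with
# approximate penultimate-style occurrence frequencies; probabilities per
# residue type sum to <= 1 (rare rotamers are dropped).
residue	chi1	chi2	chi3	chi4	probability
A					1.0
G					1.0
S	64				0.48
S	-69				0.29
S	-176				0.22
C	-65				0.50
C	-177				0.26
C	63				0.23
T	59				0.49
T	-61				0.43
T	-175				0.07
V	175				0.73
V	-64				0.20
V	63				0.06
P	30				0.56
P	-25				0.44
L	-65	175			0.59
L	-177	65			0.29
L	-172	175			0.05
L	-85	65			0.04
I	-65	170			0.60
I	-65	-60			0.15
I	62	170			0.13
I	-177	170			0.08
M	-65	-65	-70		0.19
M	-65	-65	103		0.10
M	-65	175	75		0.17
M	-65	175	180		0.13
M	-177	175	75		0.11
M	-177	175	180		0.09
M	-177	65	75		0.05
M	-65	175	-75		0.07
M	62	175	75		0.04
F	-65	-85			0.44
F	-177	80			0.34
F	62	90			0.13
Y	-65	-85			0.44
Y	-177	80			0.34
Y	62	90			0.13
W	-65	95			0.32
W	-177	-105			0.19
W	-65	-5			0.15
W	62	90			0.12
W	-177	75			0.11
H	-65	-70			0.29
H	-177	60			0.22
H	-65	80			0.16
H	62	-75			0.13
D	-70	-15			0.51
D	-177	0			0.21
D	62	10			0.14
N	-65	-20			0.38
N	-177	0			0.24
N	62	-10			0.16
E	-65	175	-10		0.32
E	-177	175	0		0.22
E	-65	-65	-40		0.18
E	62	175	0		0.08
Q	-65	175	-25		0.31
Q	-65	-65	-40		0.20
Q	-177	175	0		0.20
Q	62	175	20		0.08
K	-65	175	175	175	0.27
K	-177	175	175	175	0.18
K	-65	175	175	-65	0.12
K	-65	-65	175	175	0.12
K	62	175	175	175	0.07
R	-65	175	175	175	0.20
R	-177	175	175	175	0.14
R	-65	175	175	-85	0.12
R	-65	-65	175	175	0.11
R	-65	175	-85	175	0.09
R	62	175	175	175	0.06
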
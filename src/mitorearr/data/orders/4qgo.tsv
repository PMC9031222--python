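# provenance: Table 1: MIQGO + 4 trnQ
cox1	+
L2	+
cox2	+
K	+
D	+
atp8	+
atp6	+
cox3	+
G	+
nad3	+
A	+
R	+
N	+
S1	+
E	+
F	-
nad5	-
H	-
nad4	-
nad4L	-
T	+
P	-
nad6	+
cob	+
S2	+
nad1	-
L1	-
rrnL	-
V	-
rrnS	-
CoRe	+
M	+
I	+
Q	-
Q	-
Q	-
Q	-
nad2	+
W	+
C	-
Y	-
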
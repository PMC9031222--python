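# provenance: figure-derived/synthetic — reconstruction consistent with the published narrative (inverse transposition of trnE plus two TDRL moves from MIQGO; 37% shared common intervals with MIQGO); not the literature Bematistes order
cox1	+
L2	+
cox2	+
K	+
D	+
atp6	+
E	-
F	-
nad3	+
A	+
R	+
H	-
nad4L	-
T	+
atp8	+
cox3	+
N	+
S1	+
nad5	-
G	+
nad4	-
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
nad2	+
W	+
C	-
Y	-
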
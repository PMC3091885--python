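# Position-specific coiled-coil propensities: relative preference of each
# residue for the seven heptad positions a-g of a two-stranded coiled
# coil.  Core positions a/d favor bulky aliphatic residues, flanking
# positions e/g favor charged residues, and b/c/f are weakly selective --
# the qualitative pattern established by heptad-repeat statistics.  The
# scoring code takes the per-window geometric mean over the best heptad
# frame and converts it to a probability with a two-Gaussian transform
# calibrated against this table (see the package methods note).
# Swappable: any table with the same layout can be supplied.
# residue	a	b	c	d	e	f	g
L	3.5	1.0	1.0	3.5	0.6	1.0	0.6
I	2.5	0.8	0.8	2.5	0.6	0.8	0.6
M	2.5	0.8	0.8	2.5	0.6	0.8	0.6
V	1.8	0.8	0.8	1.8	0.6	0.8	0.6
A	1.5	1.2	1.2	1.5	1.0	1.2	1.0
F	1.2	0.8	0.8	1.2	0.6	0.8	0.6
C	0.8	0.8	0.8	0.8	0.4	0.8	0.4
W	0.3	0.8	0.8	0.3	0.4	0.8	0.4
Y	0.3	0.8	0.8	0.3	0.4	0.8	0.4
E	0.3	1.5	1.5	0.3	2.5	1.5	2.5
K	0.3	1.3	1.3	0.3	2.0	1.3	2.0
R	0.3	1.0	1.0	0.3	1.8	1.0	1.8
Q	0.3	1.3	1.3	0.3	1.8	1.3	1.8
D	0.3	1.0	1.0	0.3	1.2	1.0	1.2
N	0.3	1.0	1.0	0.3	0.8	1.0	0.8
S	0.3	1.0	1.0	0.3	0.8	1.0	0.8
T	0.3	1.0	1.0	0.3	0.8	1.0	0.8
H	0.3	1.0	1.0	0.3	0.4	1.0	0.4
G	0.1	0.3	0.3	0.1	0.15	0.3	0.15
P	0.1	0.1	0.1	0.1	0.1	0.1	0.1
X	0.5	0.5	0.5	0.5	0.5	0.5	0.5
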
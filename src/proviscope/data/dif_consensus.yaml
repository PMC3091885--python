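# Default dif-site model used for attachment-site scoring.
#
# This is the canonical 28-bp enterobacterial dif site with the standard
# 11/6/11 partition into the XerC-binding left arm, central spacer, and
# XerD-binding right arm.  Bacteroidetes dif sites differ at several
# positions; users working on a particular host group should replace the
# iupac string with a consensus derived for that group (degenerate IUPAC
# letters are fully supported).  Coordinates are 1-based inclusive.
iupac: GGTGCGCATAATGTATATTATGTTAAAT
left_arm: [1, 11]
spacer: [12, 17]
right_arm: [18, 28]
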
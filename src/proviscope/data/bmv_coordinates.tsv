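# Published coordinates of the known Bacteroidetes-associated microvirus
# (BMV) proviruses on their WGS contigs.  size_reported_bp is the provirus
# size as reported (distance between the first and last nucleotides of the
# two dif-like sites flanking the proviral region).  coordinates_consistent
# marks rows whose printed coordinate pair reproduces the reported size;
# the remaining rows are kept for reference but are unusable for
# coordinate arithmetic (partial provirus, or an apparent typographic
# error in the printed coordinates).
provirus	host	contig_accession	start	end	size_reported_bp	coordinates_consistent	note
BMV1	Bacteroides sp. 2_2_4	NZ_EQ973357	453860	460215	6356	1
BMV2	Bacteroides eggerthii DSM 20697	NZ_ABVO01000042	11368	17543	6176	1	size reported as approximate
BMV3	Bacteroides plebeius DSM 17135	NZ_ABQC02000012	89498	95972	6483	0	printed span is 6475, not 6483
BMV4	Prevotella sp. oral taxon 317 str. F0108	NZ_GG740072	687371	687398	6733	0	printed span is 28, not 6733
BMV5	Prevotella buccalis ATCC 35310	NZ_ADEG01000016	69569	75677	6109	1
BMV6a	Prevotella bergensis DSM 17361	NZ_ACKS01000073	1	700	700	1	provirus split across two contigs
BMV6	Prevotella bergensis DSM 17361	NZ_ACKS01000072	78383	83169	4787	1	provirus split across two contigs
BMV7	Prevotella bergensis DSM 17361	NZ_ACKS01000036	22909	27491	4660	0	partial provirus at contig end; size is a lower bound
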
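# Published direct-repeat recombinant frequency summaries (units: x 10^-4).
# conversion = Ade+ His+ (gene conversion), deletion = Ade+ His- (deletion).
# position: flanking = repeats flank the barrier; siteA = 0.2 kb downstream;
# siteB = 12.4 kb downstream. sd columns are standard deviations about the mean.
genotype	orientation	position	n_colonies	conversion_mean	conversion_sd	deletion_mean	deletion_sd
wild_type	IO	flanking	77	1.36	0.51	3.48	0.89
wild_type	AO	flanking	77	134.03	38.50	113.41	49.72
rad52d	IO	flanking	15	0.03	0.04	1.20	0.21
rad52d	AO	flanking	15	0.13	0.11	4.07	1.16
ori1253d	IO	flanking	15	2.33	1.86	4.80	1.58
ori1253d	AO	flanking	16	339.88	83.61	221.02	57.21
wild_type	IO	siteA	18	1.44	0.86	4.61	1.66
wild_type	AO	siteA	21	128.66	43.85	680.48	305.44
wild_type	IO	siteB	18	0.88	0.51	2.45	1.88
wild_type	AO	siteB	15	5.12	2.41	85.02	33.72
ori1253d	IO	siteB	15	1.58	0.50	4.86	2.56
ori1253d	AO	siteB	15	86.03	33.63	1094.46	443.32
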
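# Eight-origin map flanking the RTS1 barrier at the ade6 locus (chromosome 3).
# side: blocking = centromere-distal (fork arrested at the barrier in the active
# orientation); converging = centromere-proximal (opposing fork, merges at the barrier).
# distance_bp: origin midpoint to barrier. efficiency: probability of firing per S-phase.
# Only ori-1253's efficiency (0.84) is a published value; every other efficiency is a
# PLACEHOLDER chosen within the published 22-84% range (see docs/methods.md).
name	side	distance_bp	efficiency	offset_min
ori-1141	converging	186731	0.22	0.0
ori-1194	converging	134208	0.25	0.0
ori-1253	converging	75154	0.84	0.0
ori-1277	converging	51031	0.25	0.0
ori-1323	blocking	7735	0.45	0.0
ori-1338	blocking	23098	0.30	0.0
ori-1342	blocking	27172	0.25	0.0
ori-1371	blocking	55444	0.22	0.0
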
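# source: published onion Tyr-FISH mapping study; chromosome 2 signal positions (RPHC mean±SD, arm, n chromosomes measured, detection frequency %, n metaphases)
probe_id	rphc_mean	rphc_sd	arm	n_chromosomes	detection_frequency	n_metaphases
Unigene23526	79.6	2.1	short	7	57.2	24
Unigene10061	67.7	2.4	short	12	49.3	25
CL5148.Contig1	67.3	1.1	short	9	45.7	26
Unigene572	60.6	2.6	short	17	77.4	48
Unigene28076	60.0	2.6	short	7	47.3	17
CL4449.Contig1	54.0	1.7	short	6	42.8	23
Unigene25645	43.6	2.3	short	6	52.6	26
Unigene27326	23.9	1.6	short	14	45.1	19
Unigene28713	19.0	4.6	long	6	52.4	16
Unigene5305	52.3	1.5	long	14	51.6	32
mlh1	55.5	2.1	long	8	48.1	13
Unigene10683	69.6	5.7	long	8	47.8	23
Unigene23418	82.9	1.6	long	5	46.3	16
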
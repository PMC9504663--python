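# source: published onion Tyr-FISH mapping study; chromosome 6 signal positions (RPHC mean±SD, arm, n chromosomes measured, detection frequency %, n metaphases)
probe_id	rphc_mean	rphc_sd	arm	n_chromosomes	detection_frequency	n_metaphases
CL6133.Contig1	54.3	0.5	short	5	42.1	17
Unigene13813	60.7	2.9	short	9	77.8	20
Unigene7941	39.4	2.3	short	10	73.4	14
Unigene13863	24.4	1.8	long	7	43.6	21
CL4877.Contig2	33.7	3.1	long	7	46.8	21
Unigene49	29.9	2.5	long	6	43.6	22
Unigene10558	62.4	2.9	long	6	49.5	22
Unigene22659	60.0	1.9	long	5	54.8	21
CL39.Contig3	20.0	3.0	long	7	42.1	18
Unigene28149	72.3	2.7	long	6	46.7	19
Unigene8201	78.7	1.6	long	16	86.7	15
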
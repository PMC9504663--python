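# source: published onion Tyr-FISH mapping study; pseudochromosome 2 gene positions in
# 1-Mbp bins (pseudochromosome total 444 Mbp). printed=1: bin stated in the study;
# printed=0: reconstructed to be consistent with the stated marker order (order
# coincides with the linkage-group-2 order; mlh1 placed between Unigene5305 and
# Unigene10683).
marker_id	pseudochromosome	mbp_bin	printed
Unigene28076	2	6	1
Unigene23526	2	17	1
CL5148.Contig1	2	30	0
Unigene572	2	35	0
Unigene10061	2	41	1
CL4449.Contig1	2	60	0
Unigene25645	2	80	0
Unigene27326	2	100	0
Unigene28713	2	150	0
Unigene5305	2	200	0
mlh1	2	210	0
Unigene10683	2	250	0
Unigene23418	2	300	0
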
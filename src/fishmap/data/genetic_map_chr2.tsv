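# source: published onion Tyr-FISH mapping study; linkage group 2 marker order.
# printed=1: the cM value is stated in the study; printed=0: cM reconstructed to be
# consistent with the stated marker order (order is authoritative, value is not).
marker_id	linkage_group	cM	printed
Unigene28076	2	5.9	1
Unigene23526	2	9.0	1
CL5148.Contig1	2	10.5	0
Unigene572	2	12.0	0
Unigene10061	2	14.7	1
CL4449.Contig1	2	25.0	0
Unigene25645	2	35.0	0
Unigene27326	2	45.0	0
Unigene28713	2	60.0	0
Unigene5305	2	75.0	0
Unigene10683	2	85.0	0
Unigene23418	2	95.0	0
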
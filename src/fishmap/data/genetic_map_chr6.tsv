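# source: published onion Tyr-FISH mapping study; linkage group 6 marker order as
# published (long arm drawn at the top, i.e. the linkage group is upended relative to
# cytogenetic convention). printed=1: cM stated in the study; printed=0: reconstructed
# to be consistent with the stated marker order.
marker_id	linkage_group	cM	printed
Unigene8201	6	10.9	1
Unigene28149	6	13.5	1
CL39.Contig3	6	30.0	0
Unigene22659	6	45.0	0
Unigene10558	6	50.0	0
Unigene49	6	60.0	0
CL4877.Contig2	6	65.0	0
Unigene13863	6	80.0	0
Unigene7941	6	95.0	0
Unigene13813	6	101.5	1
CL6133.Contig1	6	106.7	1
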
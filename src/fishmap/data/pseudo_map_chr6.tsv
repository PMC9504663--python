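# source: published onion Tyr-FISH mapping study; pseudochromosome 6 gene positions in
# 1-Mbp bins (pseudochromosome total 315 Mbp). Order matches the 180-degree-rotated
# linkage group 6 except Unigene22659, whose position coincides with the physical
# chromosome. printed=0 bins are reconstructed to be consistent with the stated order.
marker_id	pseudochromosome	mbp_bin	printed
CL6133.Contig1	6	5	0
Unigene13813	6	20	0
Unigene7941	6	50	0
Unigene13863	6	90	0
CL4877.Contig2	6	120	0
Unigene49	6	140	0
Unigene22659	6	170	0
Unigene10558	6	180	0
CL39.Contig3	6	200	0
Unigene28149	6	270	0
Unigene8201	6	290	0
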
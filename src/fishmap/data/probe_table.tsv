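# source: published onion (Allium cepa) Tyr-FISH mapping study; probe summary (expected/observed amplicon length and probe-vs-genome identity)
marker_id	chromosome	expected_len	observed_len	identity
Unigene23526	2	1777	1772	99.6
Unigene10061	2	1517	1650	99.7
CL5148.Contig1	2	1294	1294	100
Unigene572	2	2777	2801	99.8
Unigene28076	2	1464	1465	99.7
CL4449.Contig1	2	1231	1231	100
Unigene25645	2	1188	1188	100
Unigene27326	2	1008	1008	99.7
Unigene10683	2	1160	1160	100
mlh1	2	1347	1349	99.9
Unigene23418	2	1368	1368	100
Unigene28713	2	1323	1323	100
Unigene5305	2	1588	1627	99.0
Unigene7941	6	2283	2286	99.0
Unigene13863	6	1084	1084	100
CL4877.Contig2	6	1180	1180	100
Unigene49	6	1110	1110	100
Unigene10558	6	1143	1143	100
Unigene22659	6	1457	1457	100
CL39.Contig3	6	1044	1044	100
Unigene28149	6	1236	1236	100
Unigene8201	6	3866	3866	100
Unigene13813	6	3809	3809	100
CL6133.Contig1	6	1018	1018	100
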
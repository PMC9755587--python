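gene_id	pistil_st11	pistil_st12	anther_st12	pistil_st14	silique_st17
AT5G18690	12.0	30.0	2.0	25.0	6.0
AT2G22900	6.0	15.0	1.0	12.5	3.0
AT3G21190	5.0	14.0	1.5	13.0	2.5
AT1G49750	80.0	20.0	400.0	15.0	10.0
AT2G04850	1.0	1.2	0.9	1.1	1.0
AT5G14380	0.5	0.2	900.0	0.1	0.0
AT4G37450	3.0	40.0	0.2	33.0	8.0
AT0G00000	0.0	0.0	0.0	0.0	0.0
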
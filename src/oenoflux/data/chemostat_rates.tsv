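dilution_rate_h	species	rate_mmol_gDCW_h	sd_mmol_gDCW_h
0.27	glucose	-14.8	20
0.27	fructose	-1.2	28
0.27	ethanol	17.2	3.6
0.27	glycerol	8.3	1.1
0.27	acetate	n.d.	n.d.
0.27	succinate	0.09	0.01
0.27	lactate	n.d.	n.d.
0.04	glucose	-5.0	1.4
0.04	fructose	-2.3	1.5
0.04	ethanol	12.7	1.0
0.04	glycerol	0.97	0.3
0.04	acetate	n.d.	n.d.
0.04	succinate	0.07	0.01
0.04	lactate	n.d.	n.d.
0.02	glucose	-3.0	0.6
0.02	fructose	-1.52	0.6
0.02	ethanol	7.9	0.6
0.02	glycerol	0.70	0.26
0.02	acetate	0.03	0.003
0.02	succinate	0.06	0.01
0.02	lactate	n.d.	n.d.
0.007	glucose	-2.0	0.3
0.007	fructose	-1.34	0.3
0.007	ethanol	5.92	0.6
0.007	glycerol	0.58	0.35
0.007	acetate	n.d.	n.d.
0.007	succinate	0.04	0.004
0.007	lactate	n.d.	n.d.
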
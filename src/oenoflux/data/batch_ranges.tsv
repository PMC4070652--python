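stage	window_start_h	window_end_h	species	q_min	q_max
I	8	17	glucose	-10.2	-7.3
I	8	17	fructose	-7.7	-2.2
I	8	17	ethanol	6.2	22.0
I	8	17	glycerol	1.08	3.16
I	8	17	acetate	0.07	0.19
I	8	17	succinate	0.04	0.26
I	8	17	lactate	0.04	0.08
II	20	35	glucose	-7.2	-4.4
II	20	35	fructose	-3.6	-2.2
II	20	35	ethanol	11.2	18.6
II	20	35	glycerol	0.67	1.11
II	20	35	acetate	0.09	0.15
II	20	35	succinate	0.03	0.05
II	20	35	lactate	0.03	0.04
earlyIII	30	58	glucose	-4.8	-2.7
earlyIII	30	58	fructose	-3.1	-2.31
earlyIII	30	58	ethanol	7.2	12.8
earlyIII	30	58	glycerol	0.4	0.7
earlyIII	30	58	acetate	0.02	0.1
earlyIII	30	58	succinate	0.02	0.03
earlyIII	30	58	lactate	0.02	0.06
lateIII	60	106	glucose	-2.52	0.0
lateIII	60	106	fructose	-2.07	-1.79
lateIII	60	106	ethanol	0.78	8.11
lateIII	60	106	glycerol	0.03	0.36
lateIII	60	106	acetate	0.0	0.04
lateIII	60	106	succinate	0.02	0.02
lateIII	60	106	lactate	0.003	0.003
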
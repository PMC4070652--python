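id	name	C	H	O	N	compartment
glc_e	D-glucose (extracellular)	6	12	6	0	extracellular
frc_e	D-fructose (extracellular)	6	12	6	0	extracellular
etoh_e	ethanol (extracellular)	2	6	1	0	extracellular
glyc_e	glycerol (extracellular)	3	8	3	0	extracellular
ac_e	acetate (extracellular)	2	4	2	0	extracellular
succ_e	succinate (extracellular)	4	6	4	0	extracellular
lac_e	lactate (extracellular)	3	6	3	0	extracellular
co2_e	carbon dioxide (off-gas)	1	0	2	0	extracellular
nh4_e	ammonium (extracellular)	0	3	0	1	extracellular
ala_e	L-alanine (extracellular)	3	7	2	1	extracellular
arg_e	L-arginine (extracellular)	6	14	2	4	extracellular
asp_e	L-aspartate (extracellular)	4	7	4	1	extracellular
glu_e	L-glutamate (extracellular)	5	9	4	1	extracellular
gln_e	L-glutamine (extracellular)	5	10	3	2	extracellular
ser_e	L-serine (extracellular)	3	7	3	1	extracellular
thr_e	L-threonine (extracellular)	4	9	3	1	extracellular
val_e	L-valine (extracellular)	5	11	2	1	extracellular
leu_e	L-leucine (extracellular)	6	13	2	1	extracellular
ile_e	L-isoleucine (extracellular)	6	13	2	1	extracellular
phe_e	L-phenylalanine (extracellular)	9	11	2	1	extracellular
trp_e	L-tryptophan (extracellular)	11	12	2	2	extracellular
biomass	biomass (1 g DCW unit)	0	0	0	0	extracellular
glc_c	D-glucose	6	12	6	0	cytosol
frc_c	D-fructose	6	12	6	0	cytosol
g6p	glucose 6-phosphate	6	0	0	0	cytosol
f6p	fructose 6-phosphate	6	0	0	0	cytosol
t3p	triose 3-phosphate pool	3	0	0	0	cytosol
pg3	3-phosphoglycerate	3	0	0	0	cytosol
pep	phosphoenolpyruvate	3	0	0	0	cytosol
pyr	pyruvate	3	0	0	0	cytosol
acald	acetaldehyde	2	4	1	0	cytosol
etoh_c	ethanol	2	6	1	0	cytosol
glyc_c	glycerol	3	8	3	0	cytosol
ac_c	acetate	2	4	2	0	cytosol
lac_c	lactate	3	6	3	0	cytosol
succ_c	succinate	4	6	4	0	cytosol
co2_c	carbon dioxide	1	0	2	0	cytosol
nh4_c	ammonium	0	3	0	1	cytosol
accoa	acetyl-CoA (acetyl unit)	2	0	0	0	cytosol
oaa	oxaloacetate	4	4	5	0	cytosol
p5p	pentose 5-phosphate pool	5	0	0	0	cytosol
e4p	erythrose 4-phosphate	4	0	0	0	cytosol
glu	L-glutamate	5	9	4	1	cytosol
gln	L-glutamine	5	10	3	2	cytosol
ala	L-alanine	3	7	2	1	cytosol
asp	L-aspartate	4	7	4	1	cytosol
ser	L-serine	3	7	3	1	cytosol
thr	L-threonine	4	9	3	1	cytosol
val	L-valine	5	11	2	1	cytosol
leu	L-leucine	6	13	2	1	cytosol
ile	L-isoleucine	6	13	2	1	cytosol
phe	L-phenylalanine	9	11	2	1	cytosol
trp	L-tryptophan	11	12	2	2	cytosol
lip	lipid (C18 fatty-acyl equivalent)	18	0	0	0	cytosol
rna	RNA (average nucleotide residue)	9.5	0	0	3.75	cytosol
nadh	NADH carrier (net)	0	0	0	0	cytosol
nadph	NADPH carrier (net)	0	0	0	0	cytosol
atp	ATP carrier (net)	0	0	0	0	cytosol
pyr_m	pyruvate (mitochondrial)	3	0	0	0	mitochondrion
accoa_m	acetyl-CoA (mitochondrial acetyl unit)	2	0	0	0	mitochondrion
oaa_m	oxaloacetate (mitochondrial)	4	4	5	0	mitochondrion
akg	2-oxoglutarate	5	6	5	0	mitochondrion
succoa	succinyl-CoA (succinyl unit)	4	0	0	0	mitochondrion
mal	L-malate	4	6	5	0	mitochondrion
fum	fumarate	4	4	4	0	mitochondrion
succ_m	succinate (mitochondrial)	4	6	4	0	mitochondrion
arg	L-arginine	6	14	2	4	cytosol
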
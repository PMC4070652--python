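# Default biomass composition for anaerobically grown S. cerevisiae (wine strain).
# Elemental formula per C-mol: CH_aO_bN_c.  The nitrogen content (c) and the
# molar mass per C-mol are consistent with the macromolecular composition below
# assembled over the 12 amino acids carried by the packaged network.
elemental:
  a: 1.8
  b: 0.5
  c: 0.145
molar_mass_per_cmol: 27.0   # g / C-mol, ash ("other" fraction) included
macromolecular:             # mass fractions of dry cell weight
  protein: 0.40
  carbohydrate: 0.30
  glycogen: 0.05
  trehalose: 0.03
  lipid: 0.05
  rna: 0.07
amino_acid_fractions:       # molar fractions of protein residues (12-aa model set)
  ala: 0.14
  arg: 0.06
  asp: 0.10
  glu: 0.11
  gln: 0.07
  ser: 0.09
  thr: 0.07
  val: 0.10
  leu: 0.12
  ile: 0.07
  phe: 0.05
  trp: 0.02
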
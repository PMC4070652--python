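# Synthetic must, modified MS300 recipe (per litre).  Amounts in the unit tagged
# on each component.  Amino-acid entries carry the "amino_acid" role so that
# stage presets can rescale them as a group; proline is retained but flagged
# non-assimilable under anaerobiosis.
stage_preset: stage_I
amino_acid_scale: 1.0
ammonium_present: true
components:
  glucose:              {amount: 120.0, unit: g/L}
  fructose:             {amount: 120.0, unit: g/L}
  citric_acid:          {amount: 6.0,   unit: g/L}
  malic_acid:           {amount: 6.0,   unit: g/L}
  ynb_wo_aa_ammonium:   {amount: 1.7,   unit: g/L}
  potassium_bisulphite: {amount: 60.0,  unit: mg/L}
  ergosterol:           {amount: 15.0,  unit: mg/L}
  oleic_acid:           {amount: 5.0,   unit: mg/L}
  tween_80:             {amount: 0.5,   unit: mL/L}
  nh4cl:                {amount: 306.0, unit: mg/L, role: ammonium}
  aspartic_acid:        {amount: 29.0,  unit: mg/L, role: amino_acid}
  glutamic_acid:        {amount: 80.0,  unit: mg/L, role: amino_acid}
  serine:               {amount: 52.0,  unit: mg/L, role: amino_acid}
  glutamine:            {amount: 333.0, unit: mg/L, role: amino_acid}
  histidine:            {amount: 23.0,  unit: mg/L, role: amino_acid}
  glycine:              {amount: 12.0,  unit: mg/L, role: amino_acid}
  tyrosine:             {amount: 13.0,  unit: mg/L, role: amino_acid}
  threonine:            {amount: 50.0,  unit: mg/L, role: amino_acid}
  arginine:             {amount: 245.0, unit: mg/L, role: amino_acid}
  alanine:              {amount: 97.0,  unit: mg/L, role: amino_acid}
  cysteine:             {amount: 14.0,  unit: mg/L, role: amino_acid}
  valine:               {amount: 29.0,  unit: mg/L, role: amino_acid}
  methionine:           {amount: 21.0,  unit: mg/L, role: amino_acid}
  tryptophan:           {amount: 116.0, unit: mg/L, role: amino_acid}
  phenylalanine:        {amount: 25.0,  unit: mg/L, role: amino_acid}
  isoleucine:           {amount: 22.0,  unit: mg/L, role: amino_acid}
  leucine:              {amount: 32.0,  unit: mg/L, role: amino_acid}
  lysine:               {amount: 11.0,  unit: mg/L, role: amino_acid}
  proline:              {amount: 400.0, unit: mg/L, role: amino_acid, assimilable: false}
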
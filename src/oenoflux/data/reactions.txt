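# Central carbon metabolism of S. cerevisiae under strict anaerobiosis,
# reconstructed for wine-fermentation flux analysis.
#
# Dialect: "id : lhs -> rhs" ("<->" = reversible), coefficients prefix the
# metabolite ("2 t3p"), '#' starts a comment.  An empty side is allowed
# (maintenance / sink reactions).
#
# Conventions:
#   - nadh / nadph / atp are zero-formula carrier species: only the net
#     carrier turnover is written (the oxidised partner is implicit), so
#     element bookkeeping covers C and N.
#   - exchange reactions are written excretion-positive (internal ->
#     extracellular); a negative flux is uptake, matching the sign
#     convention of the measured-rate tables.
#   - the biomass reaction is not listed here: it is assembled from a
#     BiomassComposition at model-build time.

# --- glycolysis ---
HXK  : glc_c + atp -> g6p                          | glycolysis
FRK  : frc_c + atp -> f6p                          | glycolysis
PGI  : g6p <-> f6p                                 | glycolysis
PFK  : f6p + atp -> 2 t3p                          | glycolysis    # PFK+FBA+TPI lump
GAPD : t3p -> pg3 + nadh + atp                     | glycolysis    # GAPDH+PGK lump
ENO  : pg3 <-> pep                                 | glycolysis    # PGM+ENO lump
PYK  : pep -> pyr + atp                            | glycolysis

# --- fermentative branches ---
PDC  : pyr -> acald + co2_c                        | fermentation
ADH  : acald + nadh -> etoh_c                      | fermentation
ALD  : acald -> ac_c + nadph                       | fermentation  # NADP+ acetaldehyde DH
ACS  : ac_c + 2 atp -> accoa                       | fermentation
LDH  : pyr + nadh -> lac_c                         | fermentation
GPD  : t3p + nadh -> glyc_c                        | glycerol      # G3P DH + phosphatase lump

# --- pentose phosphate pathway ---
ZWF  : g6p -> p5p + co2_c + 2 nadph                | PPP           # oxidative branch lump
TKT1 : 2 p5p <-> f6p + e4p                         | PPP           # TKT+TAL lump
TKT2 : p5p + e4p <-> f6p + t3p                     | PPP

# --- anaplerosis and mitochondrial transport ---
PYC  : pyr + co2_c + atp -> oaa                    | anaplerosis   # pyruvate carboxylase
OAAT : oaa <-> oaa_m                               | transport
PYRT : pyr <-> pyr_m                               | transport
SUCCT: succ_m -> succ_c                            | transport

# --- TCA, oxidative branch ---
PDH  : pyr_m -> accoa_m + co2_c + nadh             | TCA_oxidative
CITS : oaa_m + accoa_m -> akg + co2_c + nadh       | TCA_oxidative # CS+ACO+IDH lump
OGDH : akg -> succoa + co2_c + nadh                | TCA_oxidative
SCS  : succoa -> succ_m + atp                      | TCA_oxidative # succinyl-CoA synthetase

# --- TCA, reductive branch ---
MDH  : oaa_m + nadh <-> mal                        | TCA_reductive
FUM  : mal <-> fum                                 | TCA_reductive
FRD  : fum + nadh -> succ_m                        | TCA_reductive # fumarate reductase

# --- nitrogen assimilation and amino-acid synthesis ---
GDH  : akg + nh4_c + nadph -> glu                  | amino_acid_synthesis
GS   : glu + nh4_c + atp -> gln                    | amino_acid_synthesis
ALAT : pyr + glu <-> ala + akg                     | amino_acid_synthesis
AAT  : oaa + glu <-> asp + akg                     | amino_acid_synthesis
SERS : pg3 + glu -> ser + akg + nadh               | amino_acid_synthesis
THRS : asp + 2 atp + 2 nadph -> thr                | amino_acid_synthesis
VALS : 2 pyr + glu + nadph -> val + akg + co2_c    | amino_acid_synthesis
LEUS : 2 pyr + accoa + glu + nadph -> leu + akg + 2 co2_c  | amino_acid_synthesis
ILES : thr + pyr + glu + nadph -> ile + akg + nh4_c + co2_c | amino_acid_synthesis
PHES : 2 pep + e4p + glu + nadph -> phe + akg + co2_c      | amino_acid_synthesis
TRPS : 2 pep + e4p + p5p + ser + gln -> trp + pyr + glu + t3p + co2_c | amino_acid_synthesis
ARGS : glu + gln + asp + co2_c + 3 atp -> arg + akg + fum  | amino_acid_synthesis

# --- amino-acid degradation (enabled by pathway selection) ---
GLUD : glu -> akg + nh4_c + nadh                   | amino_acid_degradation
ARGD : arg -> glu + co2_c + 3 nh4_c                | amino_acid_degradation # arginase route

# --- macromolecule precursors and maintenance ---
LIPS : 9 accoa + 16 nadph + 8 atp -> lip           | biomass       # C18 fatty-acyl equivalent
RNAS : p5p + 3 gln + 0.75 asp + 1.5 co2_c -> rna + 3 glu | biomass # average nucleotide lump
ATPM : atp ->                                      | biomass       # non-growth maintenance

# --- exchange (excretion-positive) ---
EX_glc  : glc_c <-> glc_e                          | exchange
EX_frc  : frc_c <-> frc_e                          | exchange
EX_etoh : etoh_c <-> etoh_e                        | exchange
EX_glyc : glyc_c <-> glyc_e                        | exchange
EX_ac   : ac_c <-> ac_e                            | exchange
EX_succ : succ_c <-> succ_e                        | exchange
EX_lac  : lac_c <-> lac_e                          | exchange
EX_co2  : co2_c <-> co2_e                          | exchange
EX_nh4  : nh4_c <-> nh4_e                          | exchange
EX_ala  : ala <-> ala_e                            | exchange
EX_arg  : arg <-> arg_e                            | exchange
EX_asp  : asp <-> asp_e                            | exchange
EX_glu  : glu <-> glu_e                            | exchange
EX_gln  : gln <-> gln_e                            | exchange
EX_ser  : ser <-> ser_e                            | exchange
EX_thr  : thr <-> thr_e                            | exchange
EX_val  : val <-> val_e                            | exchange
EX_leu  : leu <-> leu_e                            | exchange
EX_ile  : ile <-> ile_e                            | exchange
EX_phe  : phe <-> phe_e                            | exchange
EX_trp  : trp <-> trp_e                            | exchange
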
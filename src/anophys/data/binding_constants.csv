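# Stepwise association constants (log10, molar scale) at the reference
# temperature / ionic strength, with reaction enthalpies for van't Hoff
# correction. Values follow the critically evaluated stability-constant
# compilations (NIST SRD 46 / Martell & Smith); the Ca-HEDTA constant is
# the adopted value within the published 8.0-8.2 range that reproduces the
# reference recipe (see docs/methods.md).
ligand,species,log10_k,delta_h_kj_mol,t_ref_c,i_ref_m
EGTA,HL,9.40,-23.4,25,0.1
EGTA,H2L,8.79,-19.2,25,0.1
EGTA,H3L,2.66,0,25,0.1
EGTA,H4L,2.00,0,25,0.1
EGTA,CaL,10.86,-33.4,25,0.1
EGTA,MgL,5.21,21.3,25,0.1
HEDTA,HL,9.81,-28.5,25,0.1
HEDTA,H2L,5.37,-15.5,25,0.1
HEDTA,H3L,2.57,0,25,0.1
HEDTA,CaL,8.04,-19.7,25,0.1
HEDTA,MgL,6.98,-13.8,25,0.1
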
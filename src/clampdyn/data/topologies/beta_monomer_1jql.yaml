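# Monomeric (mutant) Pol III beta in complex with clamp-loader subunit delta
# (PDB 1JQL; beta is chain B).  The monomer is not a closed ring: no opening
# torsion windows are defined, and the relevant observable is the A1-A2-A3
# centre-of-mass angle.  Residue ranges are the same reconstruction used for
# the dimeric clamp.
clamp_name: pol3_beta_monomer
domains:
- {label: A1, chain: B, start: 1, end: 125}
- {label: A2, chain: B, start: 126, end: 252}
- {label: A3, chain: B, start: 253, end: 366}
ring_order: [A1, A2, A3]
open_interface: [A3, A1]
torsion_quadruples: []
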
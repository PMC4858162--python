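# E. coli Pol III beta clamp homodimer (PDB 1OK7, chains A and B).
# Three clamp domains per protomer.  Residue ranges are a reconstruction of
# the visible domain decomposition (approximately equal sequential thirds of
# the 366-residue protomer); edit if better boundaries are available.
clamp_name: pol3_beta
domains:
- {label: A1, chain: A, start: 1, end: 125}
- {label: A2, chain: A, start: 126, end: 252}
- {label: A3, chain: A, start: 253, end: 366}
- {label: B1, chain: B, start: 1, end: 125}
- {label: B2, chain: B, start: 126, end: 252}
- {label: B3, chain: B, start: 253, end: 366}
ring_order: [A1, A2, A3, B1, B2, B3]
open_interface: [A3, B1]
torsion_quadruples:
- [B1, B2, B3, A1]
- [B2, B3, A1, A2]
- [B3, A1, A2, A3]
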
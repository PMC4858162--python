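# Bacteriophage RB69 gp45 homotrimer (PDB 1B77, chains A, B, C).
# Two clamp domains per 228-residue protomer; the inter-domain boundary
# (~residue 110) is a reconstruction, not part of the coordinate file.
clamp_name: gp45
domains:
- {label: A1, chain: A, start: 1, end: 110}
- {label: A2, chain: A, start: 111, end: 228}
- {label: B1, chain: B, start: 1, end: 110}
- {label: B2, chain: B, start: 111, end: 228}
- {label: C1, chain: C, start: 1, end: 110}
- {label: C2, chain: C, start: 111, end: 228}
ring_order: [A1, A2, B1, B2, C1, C2]
open_interface: [A2, B1]
torsion_quadruples:
- [B1, B2, C1, C2]
- [B2, C1, C2, A1]
- [C1, C2, A1, A2]
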
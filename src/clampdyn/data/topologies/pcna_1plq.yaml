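# S. cerevisiae PCNA homotrimer (PDB 1PLQ; a full trimer requires chains
# A, B, C — generate symmetry mates if the deposited file holds one chain).
# Two clamp domains per 258-residue protomer; the inter-domain boundary
# (~residue 117) is a reconstruction, not part of the coordinate file.
clamp_name: pcna
domains:
- {label: A1, chain: A, start: 1, end: 117}
- {label: A2, chain: A, start: 118, end: 258}
- {label: B1, chain: B, start: 1, end: 117}
- {label: B2, chain: B, start: 118, end: 258}
- {label: C1, chain: C, start: 1, end: 117}
- {label: C2, chain: C, start: 118, end: 258}
ring_order: [A1, A2, B1, B2, C1, C2]
open_interface: [A2, B1]
torsion_quadruples:
- [B1, B2, C1, C2]
- [B2, C1, C2, A1]
- [C1, C2, A1, A2]
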
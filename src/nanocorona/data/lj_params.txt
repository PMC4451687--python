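# Per-element 12-6 Lennard-Jones parameters for protein heavy atoms.
# Columns: element  sigma_nm  epsilon_kJ_per_mol
# Values are element-level magnitudes representative of CHARMM-family
# heavy-atom types (not a full atom-typed force field; see docs/methods.md).
C   0.3550  0.35
N   0.3296  0.84
O   0.3029  0.50
S   0.3564  1.88
P   0.3831  2.45
H   0.2352  0.10
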
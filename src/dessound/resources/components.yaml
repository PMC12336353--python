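# Group decompositions for the HBA/HBD components that are fully covered by
# the built-in group table (no amide, carboxyl or aromatic groups needed).
# mw: standard formula weight, g/mol; n_atoms: total atoms incl. hydrogens.
choline_chloride:
  mw: 139.62
  n_atoms: 22
  groups: {CH3: 3, CH2: 2, OH: 1, N+: 1, Cl-: 1}
ethylene_glycol:
  mw: 62.07
  n_atoms: 10
  groups: {CH2: 2, OH: 2}
diethylene_glycol:
  mw: 106.12
  n_atoms: 17
  groups: {CH2: 4, -O-: 1, OH: 2}
triethylene_glycol:
  mw: 150.17
  n_atoms: 24
  groups: {CH2: 6, -O-: 2, OH: 2}
glycerol:
  mw: 92.09
  n_atoms: 14
  groups: {CH2: 2, ">CH-": 1, OH: 3}
propane-1,2-diol:
  mw: 76.09
  n_atoms: 13
  groups: {CH3: 1, CH2: 1, ">CH-": 1, OH: 2}
menthol:
  mw: 156.27
  n_atoms: 31
  groups: {CH3: 3, ">CH-": 1, CH2_ring: 3, ">CH-_ring": 3, OH: 1}
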
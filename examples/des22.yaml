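# Choline chloride : ethylene glycol at 1:2 molar ratio ("ethaline").
# Components refer to the bundled decompositions; inline mappings with
# {name, mw, n_atoms, groups: {...}} are also accepted.
name: DES22
hba: choline_chloride
hbd: ethylene_glycol
ratio: "1:2"
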
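# Species definition for the foldon / biotinylated-foldon trimer mixture.
#
# A proteoform needs a formula and/or a monoisotopic mass; the biotinylated
# form is declared by mass and atom count because its vendor formula is not
# self-consistent (the package warns instead of silently correcting).
proteoforms:
  - id: F
    name: T4 fibritin foldon
    formula: C142H214N36O41
  - id: bF
    name: biotinylated T4 fibritin foldon
    monoiso_mass: 3594.82
    atom_count: 505

# Observed charge state per oligomer role.
charges:
  trimer: 5
  dimer: 3
  monomer: 2
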
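# Roster of training complexes (PDB id + partner molecules). The package
# never downloads structures; users who hold the PDB entries can regenerate
# features with `apis featurize`. Chain splits follow the first/second
# molecule convention of the published roster.
note: >-
  The source roster text counts 17 complexes but prints 15 entries; the 15
  printed entries are recorded here and the discrepancy is flagged.
complexes:
  - {pdb_id: 1a4y, first: Angiogenin, second: Ribonuclease Inhibitor}
  - {pdb_id: 1a22, first: Human growth hormone, second: Human growth hormone binding protein}
  - {pdb_id: 1ahw, first: Immunoglobulin Fab 5G9, second: Tissue factor}
  - {pdb_id: 1brs, first: Barnase, second: Barstar}
  - {pdb_id: 1bxi, first: Colicin E9 Immunity Im9, second: Colicin E9 DNase}
  - {pdb_id: 1cbw, first: BPTI Trypsin inhibitor, second: Chymotrypsin}
  - {pdb_id: 1dan, first: Blood coagulation factor VIIA, second: Tissue factor}
  - {pdb_id: 1dvf, first: Idiotopic antibody FV D1.3, second: Anti-idiotopic antibody FV E5.2}
  - {pdb_id: 1fc2, first: Fc fragment, second: Fragment B of protein A}
  - {pdb_id: 1fcc, first: Fc (IGG1), second: Protein G}
  - {pdb_id: 1gc1, first: Envelope protein GP120, second: CD4}
  - {pdb_id: 1jrh, first: Antibody A6, second: Interferon-gamma receptor}
  - {pdb_id: 1vfb, first: Mouse monoclonal antibody D1.3, second: Hen egg lysozyme}
  - {pdb_id: 2ptc, first: BPTI, second: Trypsin}
  - {pdb_id: 3hfm, first: Hen Egg Lysozyme, second: lg FAB fragment HyHEL-10}
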
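{
  "_comment": "Silver-coordination donor atoms per nucleotide residue. aromatic_N: ring nitrogens (purine N1/N3/N7, pyrimidine N3); carbonyl_O: exocyclic keto oxygens; phosphate_O: non-bridging phosphate oxygens; phosphate_bridging: ester oxygens, excluded from detection by default.",
  "DA": {"aromatic_N": ["N1", "N3", "N7"], "carbonyl_O": [], "phosphate_O": ["OP1", "OP2"], "phosphate_bridging": ["O5'", "O3'"]},
  "DG": {"aromatic_N": ["N1", "N3", "N7"], "carbonyl_O": ["O6"], "phosphate_O": ["OP1", "OP2"], "phosphate_bridging": ["O5'", "O3'"]},
  "DC": {"aromatic_N": ["N3"], "carbonyl_O": ["O2"], "phosphate_O": ["OP1", "OP2"], "phosphate_bridging": ["O5'", "O3'"]},
  "DT": {"aromatic_N": ["N3"], "carbonyl_O": ["O2", "O4"], "phosphate_O": ["OP1", "OP2"], "phosphate_bridging": ["O5'", "O3'"]},
  "A": {"aromatic_N": ["N1", "N3", "N7"], "carbonyl_O": [], "phosphate_O": ["OP1", "OP2"], "phosphate_bridging": ["O5'", "O3'"]},
  "G": {"aromatic_N": ["N1", "N3", "N7"], "carbonyl_O": ["O6"], "phosphate_O": ["OP1", "OP2"], "phosphate_bridging": ["O5'", "O3'"]},
  "C": {"aromatic_N": ["N3"], "carbonyl_O": ["O2"], "phosphate_O": ["OP1", "OP2"], "phosphate_bridging": ["O5'", "O3'"]},
  "U": {"aromatic_N": ["N3"], "carbonyl_O": ["O2", "O4"], "phosphate_O": ["OP1", "OP2"], "phosphate_bridging": ["O5'", "O3'"]}
}
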
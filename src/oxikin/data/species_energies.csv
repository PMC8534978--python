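label,energy,unit,role
CA,-2836114.23,kJ_per_mol,parent
CA-O15-radical,-2834498.68,kJ_per_mol,radical
CA-O18-radical,-2834506.32,kJ_per_mol,radical
H-atom,-1312.28,kJ_per_mol,hydrogen_atom
OA,-856.390,hartree,parent
OA-C8-radical,-855.757199,hartree,radical
OA-C11-radical,-855.757275,hartree,radical
H-atom-hartree,-0.498,hartree,hydrogen_atom
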
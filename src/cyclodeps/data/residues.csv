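# Default residue alphabet for cyclic depsipeptide annotation.
# Formulas are DEHYDRATED residues (free acid minus H2O), so a cyclic
# peptide formula is the plain element-wise sum of its residues.
# Columns: name, Hill formula, linkage_class (amino|hydroxy)
# Lxx is the mass-ambiguity code for Leu/Ile/MeVal, which share C6H11NO
# and cannot be told apart from MS2 data alone.
Phe, C9H9NO, amino
Leu, C6H11NO, amino
Ile, C6H11NO, amino
MeVal, C6H11NO, amino
Lxx, C6H11NO, amino
Hba, C4H6O2, hydroxy
Lac, C3H4O2, hydroxy
Hda, C10H18O2, hydroxy
Hdda, C12H22O2, hydroxy
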
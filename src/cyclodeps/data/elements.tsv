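# Monoisotopic atomic masses (Da) of the most abundant isotope.
# Values follow the IUPAC/CODATA recommendations, quoted to at least 7
# decimal places so that derived ion m/z values are stable to 1e-4.
# Columns: symbol <TAB> monoisotopic_mass
H	1.0078250319
C	12.0000000000
N	14.0030740052
O	15.9949146221
Na	22.9897692809
S	31.9720707300
K	38.9637064864
P	30.9737615120
F	18.9984031630
Cl	34.9688527100
Br	78.9183375600
I	126.9044719000
Se	79.9165218000
Si	27.9769265350
B	11.0093055000
Fe	55.9349375000
Mg	23.9850417000
Ca	39.9625908600
Zn	63.9291420000
Cu	62.9295977000
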
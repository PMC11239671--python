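# Limiting (infinite-dilution) molar ionic conductivities at 25 C, aqueous.
# lambda0 in S*cm^2/mol per mole of ion (i.e. |z| * equivalent conductivity).
# Sources: CRC Handbook of Chemistry and Physics (95th ed.) tables of limiting
# ionic conductivities for the inorganic ions; relative-mobility compilations
# for the organic anions and NMDG+ commonly used in patch-clamp junction-
# potential calculators (Ng & Barry 1995, J Neurosci Methods 56:37-41).
# version: 1
ion,z,lambda0_S_cm2_per_mol
H,1,349.8
Li,1,38.7
Na,1,50.1
K,1,73.5
Rb,1,77.8
Cs,1,77.3
NH4,1,73.7
TEA,1,32.7
NMDG,1,33.0
Tris,1,29.5
Mg,2,106.1
Ca,2,119.0
Ba,2,127.3
Cl,-1,76.35
Br,-1,78.1
I,-1,76.8
F,-1,55.4
NO3,-1,71.5
OH,-1,198.6
HCO3,-1,44.5
SO4,-2,160.0
acetate,-1,40.9
gluconate,-1,24.3
isethionate,-1,38.2
methanesulfonate,-1,48.8
aspartate,-1,30.9
glutamate,-1,26.0
HEPES,-1,22.1
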
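# Gibbs free energies of formation at biochemical standard conditions
# (pH 7, 1 M, 25 degC), kJ/mol. Dissolved species are used for the gases
# (O2, CO2, N2). H+ is priced at its pH-7 value. CH2O (generic biomass)
# is one sixth of the glucose value. The thiosulfate entry is calibrated
# against published aerobic thiosulfate-oxidizer efficiencies (see
# docs/methods.md); the uncalibrated literature value is -513.4.
# Carrier entries encode only the oxidized->reduced increment
# (reduced form minus oxidized form); the oxidized forms are pinned at 0.
species	dgf0_kj_per_mol
H2S	-27.87
S0	0.0
SO4	-744.63
S2O3	-523.2
O2	16.4
H2O	-237.18
H+	-39.87
CO2	-386.02
CH2O	-152.87
NO3	-111.34
N2	18.18
NH4	-79.37
NAD+	0.0
NADH	60.99
FAD	0.0
FADH2	42.65
Fd_ox	0.0
Fd_red	38.88
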
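component	kind	molar_mass
GSF	API	352.77
IBP	API	206.28
IMC	API	357.79
NPX	API	230.26
NIF	API	346.34
PCM	API	151.16
SIM	API	418.60
EUD	polymer	212000
HPMCAS	polymer	120000
PDL	polymer	16400
PLGA50	polymer	9877
PLGA75	polymer	12900
PVA	polymer	32000
PVPK12	polymer	2500
PVPK25	polymer	25700
PVPK30	polymer	49000
PVPVAc64	polymer	65000
SOL	polymer	118000
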
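id	equation	lb	ub	tag
EX_photon	-> E_in	0.0	100.0	
EX_CO2	-> CO2_in	0.0	10.0	
EX_NO3	-> NO3_in	0.0	5.0	
CARBOXYLATION	CO2_in + E_in -> PGA	0.0	1000.0	carboxylation
OXYGENATION	CO2_in + E_in -> 0.5 PGA	0.0	1000.0	oxygenation
STARCH_SYNTH	PGA -> STARCH	0.0	1000.0	starch_synthesis
SUCROSE_SYNTH	PGA -> SUCROSE	0.0	1000.0	sucrose_synthesis
BIOMASS	1.29 STARCH + 0.5 SUCROSE + 0.4 NO3_in ->	0.0	1000.0	biomass
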
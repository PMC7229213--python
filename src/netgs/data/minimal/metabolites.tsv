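id
E_in
CO2_in
NO3_in
PGA
STARCH
SUCROSE
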
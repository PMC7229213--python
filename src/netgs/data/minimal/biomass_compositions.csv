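metabolite,coefficient,accession,environment
STARCH,-1290.0,reference,E1
SUCROSE,-500.0,reference,E1
NO3_in,-400.0,reference,E1
STARCH,-1200.0,reference,E2
SUCROSE,-500.0,reference,E2
NO3_in,-300.0,reference,E2
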
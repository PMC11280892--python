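Oz
F4
P8
CP2
Cz
Fp2
P2
FC5
T7
O1
FC6
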
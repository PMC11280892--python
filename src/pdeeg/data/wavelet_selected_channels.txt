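TP7
TP9
TP10
FC3
FC4
FC5
PO7
PO8
CP3
CP5
P1
P3
P4
P5
P6
P8
AF3
C4
F5
Oz
O1
O2
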
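step_id,xray_avg,nmr_avg,experiment
C1pG2,1.05,0.10,0.37
G2pC3,0.75,0.02,0.26
C3pG4,0.24,0.10,0.46
G4pA5,0.21,0.10,0.24
A5pA6,-0.03,0.09,0.12
A6pT7,0.00,0.00,0.00
T7pT8,0.06,-0.02,0.02
T8pC9,0.00,0.03,0.12
C9pG10,0.11,0.10,0.52
G10pC11,4.10,0.01,0.37
C11pG12,0.49,0.00,0.52
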
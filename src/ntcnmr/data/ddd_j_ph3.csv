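step_id,xray_avg,nmr_avg,experiment
C1pG2,4.49,1.92,6.27
G2pC3,3.43,1.66,3.64
C3pG4,2.52,1.91,5.58
G4pA5,2.70,1.92,4.00
A5pA6,1.59,1.89,2.95
A6pT7,1.85,1.70,2.53
T7pT8,2.00,1.51,2.69
T8pC9,1.70,1.68,3.07
C9pG10,2.04,1.91,5.07
G10pC11,10.06,1.64,4.04
C11pG12,3.64,1.57,5.21
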
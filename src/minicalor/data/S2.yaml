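# Minisensor S2 calibration parameters.
# Gains: K1, K2 in mV/W; K3, K4 in K/W.  Time constants in s.
label: S2
K1: 132.40
K2: -42.22
K3: 8.67
K4: 9.82
tau1: 84.0
tau2: 8.2
tau1_star: 73.5
tau2_star: 96.1
tau3_star: 0.0
tau4_star: 18.4
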
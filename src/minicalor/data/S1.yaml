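# Minisensor S1 calibration parameters.
# Gains: K1, K2 in mV/W; K3, K4 in K/W.  Time constants in s.
label: S1
K1: 117.98
K2: -51.33
K3: 8.98
K4: 11.92
tau1: 80.8
tau2: 9.5
tau1_star: 64.4
tau2_star: 108.2
tau3_star: 0.0
tau4_star: 22.2
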
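# A single irregularity in an otherwise uniform two-mass array (SI units).
# Every element is individually damped; element 200 merely has MORE damping
# (gamma0 lower by 0.15).  The irregularity reflects travelling waves and
# the array becomes a global self-sustaining oscillator.  The uniform
# gamma0 level at which this happens depends on the element parameter
# table; the value below is the calibrated level for the repository's
# place-map family (levels quoted for other tables do not transfer).
name: intermezzo3
variant: nk
unit: s
n: 351
a: 0.2
d1: 0.1
f1_hz: 1000.0
f_base: 10000.0
f_apex: 140.0
duct_length: 100.0
t_end: 0.2
dt: 5.0e-6
m1: 0.044
m2: 0.0073
g: 1.0
alpha_sat: 2.0e-5
beta_sat: 0.1
gamma0: 1.05           # uniform feedback gain (table-dependent level)
notch_element: 200
notch_delta: -0.15     # gamma0_200 = gamma0 - 0.15: a pure irregularity
kick: 0.1              # ydot_200(0)
decimate: 10
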
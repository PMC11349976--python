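# Bidirectionally coupled Hopf pair: BM and OC units, each damped in
# isolation, coupled above the analytic threshold c* = sqrt(0.5*0.05).
name: pair
f: 0.5
alpha_bm: -0.5
alpha_oc: -0.05
beta: -0.5
c: 0.3
z_bm0: [1.0, 0.0]
z_oc0: [1.0, 0.0]
t_end: 200.0
dt: 0.01
# default sweep spanning below / near / above the threshold (~0.1581)
c_sweep: [0.05, 0.16, 0.30]
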
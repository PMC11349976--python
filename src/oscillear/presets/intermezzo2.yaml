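# Two-mass (BM + TM) element box with a single active element (SI units).
# gamma0 scales the saturating feedback force; larger gamma0 means less
# damping.  Element 200 at gamma0 = 2.0 is self-sustaining, all others are
# passive at 0.5.  Stiffness/damping place-maps are the repository's
# calibrated family (the original per-element table is external).
name: intermezzo2
variant: nk
unit: s
n: 351
a: 0.2
d1: 0.1
f1_hz: 1000.0          # omega1 = 2000*pi rad/s
f_base: 10000.0        # Hz
f_apex: 140.0
duct_length: 100.0
t_end: 0.2             # s
dt: 5.0e-6
m1: 0.044
m2: 0.0073
g: 1.0
alpha_sat: 2.0e-5
beta_sat: 0.1
gamma0: 0.5
active_element: 200
active_gamma0: 2.0
kick: 1.0e-4           # ydot_200(0)
decimate: 10
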
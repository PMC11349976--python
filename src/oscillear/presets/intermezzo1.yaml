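# Van der Pol box with a single active oscillator (millisecond / kHz units).
# One element (200) is given negative small-signal damping; it launches a
# wave that reflects at the stapes and builds a standing wave driving the
# middle ear: a spontaneous emission.
name: intermezzo1
variant: vdp
unit: ms
n: 351
a: 0.2                 # pressure scaling constant
kappa: 1.0             # force per pressure, m^2/kg
d1: 0.1                # middle-ear damping
f1_khz: 1.0            # middle-ear resonance (omega1 = 2*pi kHz)
f_base: 10.0           # kHz at element 2
f_apex: 0.14           # kHz at element n
duct_length: 100.0     # folded duct geometry (repository calibration)
t_end: 50.0            # ms
dt: 0.005              # ms (5 microseconds)
alpha: -0.1            # passive damping parameter, elements 2..n
beta: 20.0
active_element: 200
active_alpha: 0.1      # makes element 200 self-sustaining
kick: 0.01             # xdot_200(0)
decimate: 10
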
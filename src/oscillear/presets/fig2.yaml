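# Noise-driven Van der Pol pipeline: drive the active oscillator with
# narrow-band noise (centre = its own fundamental, width 0.5*f0), add white
# noise to the output, band-pass around the emission peak and around a
# noise-only peak, and histogram the filtered signals.  The emission band
# gives a double-peaked amplitude distribution; the noise band a single
# zero-centred mode.  Drive and noise levels are repository conventions
# chosen to keep the emission peak >= 20 dB above the noise floor.
name: fig2
omega: 6.283185307179586     # 2*pi
alpha: 1.0
beta: 4.0
x0: 0.001
v0: 0.0
t_end: 2000.0
dt: 0.01
drive_amplitude: 0.1         # RMS of the narrow-band drive force
white_amplitude: 0.05        # std of white noise added to the output
bandwidth_factor: 0.5        # drive bandwidth = factor * f0
filter_width_factor: 0.1     # analysis band width = factor * f0
seed: 7
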
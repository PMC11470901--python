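# Seizure-onset waveform phi(t) = r0 e^{i theta(t)} + r(t) e^{i a0 t}:
# theta is the band-limited phase step relaxing past the observation point
# (fast transient at ~ k_m/sqrt(2) rad per unit time), r(t) a logistic ramp
# to the limit-cycle amplitude.  Time scale arbitrary; illustrative values.
a2: 1.0
phi_l: 1.0
k_m: 30.0
a0: 0.15
r0: 0.1
x_obs: -10.0
ramp: {plateau: 1.0, t_mid: 30.0, tau: 4.0}
t_max: 70.0
n_samples: 7000
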
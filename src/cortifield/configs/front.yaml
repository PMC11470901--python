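# Half-plane front experiment: quiescent left half (eps), limit-cycle right
# half (phi_l), bistable quintic bulk, boundary recruitment sweep over a2.
# Short run: the bulk inherits the radial instability of the second-order
# collapse, so long runs corrupt the field behind the front.
grid: {nx: 240, ny: 8, dx: 0.25, dy: 0.25, boundary: reflecting}
c1: 0.1
phi_l: 1.0
eps: 1.0e-3
a2_sweep: [0.5, 1.0, 2.0]
t_end: 12.0
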
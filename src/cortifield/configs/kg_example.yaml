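# Example simulation config: Klein-Gordon plane wave on a periodic grid.
model: kg
grid: {nx: 64, ny: 64, dx: 1.0, dy: 1.0, boundary: periodic}
params: {c: 1.0, m: 0.0}
ic: {type: plane_wave, phi0: 1.0, k: [0.19634954084936207, 0.0]}
dt: auto
n_steps: 2000
stride: 10
seed: 0
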
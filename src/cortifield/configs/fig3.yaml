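# Phase-wave fields around the limit-cycle state: plane-slope phase plus
# harmonic phase waves obeying omega^2 = c1 |k|^2.  Illustrative settings
# matching the qualitative panels (single wave, different-frequency wave,
# mixture); grid size/coefficients are package choices.
c1: 1.0
c2: -1.0
c3: 1.0
t: 0.0
grid: {nx: 96, ny: 96, dx: 0.25, dy: 0.25, boundary: periodic}
panels:
  - {name: single, b2: 0.5, b3: 0.0, harmonics: []}
  - {name: harmonic, b2: 0.0, b3: 0.0, harmonics: [{A0: 1.0, k: [1.0, 0.0]}]}
  - {name: mixture, b2: 0.3, b3: 0.2,
     harmonics: [{A0: 0.7, k: [0.8, 0.0]}, {A0: 0.4, k: [0.0, 1.2]}]}
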
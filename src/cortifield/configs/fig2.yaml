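# Power over frequency: P(f) = 1 / (c0 + (a2/c^2) f^2 + (a3/c^4) f^4).
# Units map: 1 model frequency unit = 1 Hz at wave speed c = 10 mm/s.
# The coefficient ratio places the quadratic/quartic crossover at
# f* = c*sqrt(a2/a3) = 100 Hz; slope bands default to [f*/100, f*/10]
# (expected slope -2) and [10 f*, 100 f*] (expected slope -4).
c0: 1.0e-4
a2: 1.0
a3: 1.0e-4
c: 1.0
hz_per_unit: 1.0
f_min: 0.1
f_max: 100000.0
n_samples: 4000
low_band: [1.0, 10.0]
high_band: [1000.0, 10000.0]
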
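# As fig5 but with inverse-squared-distance connectivity between tile
# centres (exponent 1 also supported; the figure uses squared distance).
tiling: {P: 25, Q: 25}
tile_grid: {nx: 8, ny: 8, dx: 1.0, dy: 1.0, boundary: periodic}
connectivity: dist2
strength: 1.0
indices: [0, 1, 2, 624]
base: {k: [0.7853981633974483, 0.7853981633974483]}
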
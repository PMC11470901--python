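# Self-contained patterns of the 25x25 nearest-neighbour tessellation
# (625 eigenmodes); four pattern indices rendered.  Within-tile base field
# is a diagonal plane wave; tile lattice size is a package choice.
tiling: {P: 25, Q: 25}
tile_grid: {nx: 8, ny: 8, dx: 1.0, dy: 1.0, boundary: periodic}
connectivity: nn
strength: 1.0
indices: [0, 1, 2, 624]
base: {k: [0.7853981633974483, 0.7853981633974483]}
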
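# Small demonstration run: 3 + 3 subjects on coarse 2 mm grids.
seed = 11
n_older = 3
n_stroke = 3
shape = [32, 32, 32]
voxel_size_mm = [2.0, 2.0, 2.0]
out_dir = "penumbra_demo"
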
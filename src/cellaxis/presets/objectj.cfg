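# ObjectJ/ChainTracer result tables (ImageJ plugin; 0-based pixel
# coordinates).
[meta]
base = 0

[mesh]
cell_id = Cell
frame_id = Slice
x = X
y = Y

[spot]
spot_id = Spot
frame_id = Slice
x = X
y = Y
intensity = Mean
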
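# MicrobeJ result-table export (ImageJ plugin; 0-based pixel coordinates).
# Column names follow the flattened result tables MicrobeJ writes per
# particle/maxima; adjust the mapping if your export uses different headers.
[meta]
base = 0

[mesh]
cell_id = NAME
frame_id = POSITION
x = SHAPE.x
y = SHAPE.y

[spot]
spot_id = NAME
frame_id = POSITION
x = LOCATION.x
y = LOCATION.y
intensity = INTENSITY.ch1

[track]
track_id = TRAJECTORY.id
frame_id = POSITION
time = TIME
length = SHAPE.length
width = SHAPE.width
fluor = INTENSITY.ch1
parent = PARENT
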
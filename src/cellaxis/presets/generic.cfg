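# Generic delimited-table dialect. Coordinates are 0-based pixels with the
# pixel center at integer positions. Left side: standard field, right side:
# source column name.
[meta]
base = 0

[mesh]
cell_id = cell
frame_id = frame
x = x
y = y

[spot]
spot_id = spot
frame_id = frame
x = x
y = y
channel = channel
intensity = intensity
time = time

[object]
object_id = object
frame_id = frame
x = x
y = y

[track]
track_id = track
frame_id = frame
time = time
length = length
width = width
fluor = fluor
parent = parent
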
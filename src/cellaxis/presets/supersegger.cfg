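# SuperSegger exported cell tables (MATLAB-based; 1-based pixel coordinates,
# converted to 0-based on import).
[meta]
base = 1

[mesh]
cell_id = cell_id
frame_id = frame
x = contour_x
y = contour_y

[spot]
spot_id = focus_id
frame_id = frame
x = focus_x
y = focus_y
intensity = focus_intensity

[track]
track_id = cell_id
frame_id = frame
time = time_s
length = length
width = width
fluor = fluorescence
parent = mother_id
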
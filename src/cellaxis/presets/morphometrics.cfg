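# Morphometrics exported contour tables (MATLAB-based; 1-based pixel
# coordinates, converted to 0-based on import).
[meta]
base = 1

[mesh]
cell_id = cellID
frame_id = frame
x = Xcont
y = Ycont

[track]
track_id = cellID
frame_id = frame
time = time
length = length
width = width
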
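"""Build detector training regions from a manual vessel tracing.

An annotated polyline is converted into the overlapping square regions a
detector trains on: centers sampled every `stride` px of arc length, both
endpoints always included, every box carrying the polyline's class label.
"""
import vesselkit as vk

trace = vk.Polyline(((12.0, 20.0), (80.0, 55.0), (150.0, 60.0), (210.0, 110.0)))
regions = vk.boxes_from_polyline(trace, box_size=32, stride=16)

L = vk.polyline_length(trace)
print(f"polyline length: {L:.1f} px -> {len(regions.boxes)} overlapping 32x32 regions")
print("first three centers:",
      [(round(b.cx, 1), round(b.cy, 1)) for b in regions.boxes[:3]])
print("consecutive centers are <= one stride apart and the union of regions"
      " covers the whole trace.")
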
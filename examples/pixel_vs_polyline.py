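"""Why label-aware polyline measurement beats pixel-based skeletons on debris.

Two renderings of the same vessel network are measured twice — once with the
classical skeleton method, once with the polyline pipeline. Adding bright
elongated debris inflates the skeleton measurement (the size filter cannot
reject vessel-shaped clumps) while the polyline pipeline, which knows the
debris class label, barely moves.
"""
import vesselkit as vk

base = dict(n_debris=0, n_out_of_plane=0, seed=11)
clean = vk.make_scene(vk.SceneParams(**base))
dirty = vk.make_scene(vk.SceneParams(**{**base, "n_debris": 8,
                                        "debris_size_px": (20.0, 40.0)}))
truth = clean.truth_vessel_length_px

for name, scene in (("clean scene", clean), ("with debris", dirty)):
    pixel = vk.pixel_based_length(scene.image)
    det = vk.oracle_detect(scene.truth, seed=3)
    poly = sum(vk.polyline_length(p) for p in vk.reconstruct(det, scene.image))
    print(f"{name:12s}  truth {truth:7.1f} px   pixel-based {pixel:7.1f} px   "
          f"polyline {poly:7.1f} px")
print("pixel-based length grows with debris; the polyline measurement is"
      " stable because debris boxes carry their own label and are excluded.")
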
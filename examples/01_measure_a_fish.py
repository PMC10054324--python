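"""Measure a free-swimming fish from a synthetic stereo frame pair.

Builds a calibrated 120 mm-baseline rig, projects a 300 mm fish at 1.5 m
into both cameras with half-pixel box jitter, stereo-matches the detections
and triangulates the matched box corners into metric size and distance.
"""

from stereofauna import geometry, synthetic
from stereofauna.stereo_match import match_detections, measure, rectify_detection

rig = synthetic.make_rig()            # 120 mm baseline, f = 1400 px
rect = geometry.rectify(rig)

fish = synthetic.TargetSpec(label="Gadus morhua", length_mm=300.0,
                            height_mm=100.0,
                            waypoints=((0, 0.0, 0.0, 1500.0),
                                       (1, 0.0, 0.0, 1500.0)))
config = synthetic.SceneConfig(rig=rig, targets=(fish,), n_frames=1,
                               noise=synthetic.NoiseSpec(jitter_px=0.5),
                               seed=0)
_, detections = synthetic.simulate_fish_scene(config)

left = [rectify_detection(d, rect) for d in detections if d.camera == "left"]
right = [rectify_detection(d, rect) for d in detections if d.camera == "right"]
matches, _, _ = match_detections(left, right)
m = measure(matches[0], rect)

print(f"matched 1 pair: score={matches[0].score:.2f} "
      f"theta={matches[0].theta_deg:.3f} deg iou={matches[0].iou:.3f}")
print(f"width  = {m.width_mm:6.1f} mm  (true 300)")
print(f"height = {m.height_mm:6.1f} mm  (true 100)")
print(f"range  = {m.distance_mm:6.1f} mm  (true 1500)")
# The few-mm deviations come from the 0.5 px box jitter; at 1.5 m each pixel
# of disparity error is worth about z^2/(f*B) = 13 mm of depth.
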
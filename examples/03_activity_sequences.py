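"""Reduce a rendered clip to activity sequences via background subtraction.

A fish crosses a static-noise background between frames 12 and 30; the
per-pixel Gaussian-mixture background model flags the moving silhouette and
the extractor returns the containing frame interval.
"""

import numpy as np

from stereofauna import synthetic
from stereofauna.activity import (ActivityParams, extract_sequences,
                                  foreground_fraction)

rig = synthetic.make_rig(focal_px=120.0, image_size=(128, 96))
fish = synthetic.TargetSpec(label="Clupeidae", length_mm=300.0,
                            height_mm=120.0,
                            waypoints=((12, -250.0, 0.0, 1200.0),
                                       (30, 250.0, 0.0, 1200.0)))
config = synthetic.SceneConfig(rig=rig, image_size=(128, 96), targets=(fish,),
                               n_frames=40, seed=0)
frames = synthetic.render_frames(config, background_noise=2.0)

params = ActivityParams(median_kernel=3, history=20, min_length=3,
                        merge_gap=5)
fractions = foreground_fraction(frames, params)
sequences = extract_sequences(fractions, params)

print("peak foreground fraction:", float(np.max(fractions)))
for s in sequences:
    print(f"activity sequence: frames [{s.start}, {s.end}], "
          f"mean foreground fraction {s.mean_fraction:.4f}")
# The single extracted interval brackets the fish's true visibility span;
# only those frames would be passed on to the detector.
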
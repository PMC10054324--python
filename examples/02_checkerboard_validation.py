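"""Validate stereo size measurements with a 9x8 / 50 mm checkerboard.

Projects noisy synthetic boards at four working distances, triangulates the
inner corners, and reports the horizontal/vertical measurement error per
distance bin — the error grows with distance as z^2/(f*B).
"""

import logging

import numpy as np

from stereofauna import geometry, synthetic

# 0.5 px corner noise occasionally exceeds the 2 px epipolar warning gate;
# the rows are averaged, so silence the per-board warnings here.
logging.getLogger("stereofauna.geometry").setLevel(logging.ERROR)
from stereofauna.validation import BoardSpec, board_errors, error_vs_distance

rig = synthetic.make_rig()
rect = geometry.rectify(rig)
rng = np.random.default_rng(0)

pairs = []
for z in (500.0, 1000.0, 1500.0, 2000.0):
    for k in range(25):
        _, lp, rp = synthetic.project_checkerboard(
            rig, position=(float(rng.uniform(-30, 30)), 0.0, z),
            noise_sigma=0.5, seed=int(rng.integers(2**31)))
        pairs.append((f"z{z:.0f}_{k}", lp, rp))

report = board_errors(pairs, BoardSpec(), rect)
print(f"overall: horizontal {report.mean_horizontal_mm:.2f} mm, "
      f"vertical {report.mean_vertical_mm:.2f} mm")
print(error_vs_distance(report, bin_width_mm=500.0).to_string(index=False))
# Each row is one 0.5 m distance bin; with 0.5 px corner noise the mean
# inter-corner measurement error rises from well under a millimetre at
# 0.5 m to a few millimetres at 2 m.
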
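"""Summarize an annotation manifest and build a hard-day holdout split.

Writes a small VIAME-style track manifest, reads it back, prints the
per-class image/box/track summary, and splits the images 85/15 with one
recording day forced entirely into validation.
"""

import tempfile
from pathlib import Path

from stereofauna.dataset import (images_from_annotations, read_annotations,
                                 split, summarize, write_annotations,
                                 TrackAnnotation)
from stereofauna.detection import BoundingBox

tracks = []
tid = 0
for day in range(5):
    for k in range(4):  # four tracks per day, 5 boxes each
        frames = list(range(5))
        boxes = [BoundingBox(10 * k, 0, 10 * k + 8, 8)] * 5
        ids = [f"day{day}/img{day:02d}{k}{f}.png" for f in frames]
        label = ["Gadus morhua", "Clupeidae"][k % 2]
        tracks.append(TrackAnnotation(tid, label, frames, boxes, ids,
                                      day=f"day{day}"))
        tid += 1

path = Path(tempfile.mkdtemp()) / "manifest.csv"
write_annotations(tracks, path)
annotations = read_annotations(path)

summary = summarize(annotations)
print(summary.per_class)
print(f"totals: {summary.total_images} images, {summary.total_boxes} boxes, "
      f"{summary.total_tracks} tracks")

images = images_from_annotations(annotations)
train, val = split(images, ratio=0.85, seed=0, holdout_days=["day3"])
print(f"train {len(train)} / val {len(val)} images "
      f"(day3's {sum(i.startswith('day3') for i in val)} images all in val)")
# Forcing whole days into validation keeps never-seen recording conditions
# out of training, making the validation score harder and more honest.
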
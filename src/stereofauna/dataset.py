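"""Annotation-manifest handling: VIAME-style tracks, summaries and splits.

The annotation tooling groups the bounding boxes of one animal into a
*track*; manifests arrive as VIAME-style CSV (track id, image id, frame, box
corners, class). This module reads and writes that format, produces
per-class manifest summaries (images / boxes / tracks), and performs the
per-image train/validation split with an optional hard-day holdout: entire
recording days can be forced into validation so the validation set contains
conditions never seen in training.

``REFERENCE_MANIFEST`` ships the per-class counts of the ten-taxon Baltic
Sea observatory manifest the synthetic generator emulates, for use as a
worked example and summary cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .detection import BoundingBox

__all__ = ["TrackAnnotation", "ManifestSummary", "read_annotations",
           "write_annotations", "summarize", "summary_from_class_rows",
           "split", "images_from_annotations", "REFERENCE_MANIFEST",
           "REFERENCE_SPLIT", "DEFAULT_CLASSES"]

from .synthetic import DEFAULT_CLASSES

# Per-class (images, bounding boxes, tracks) of the reference manifest.
REFERENCE_MANIFEST = {
    "Ctenophora": (20695, 28800, 203),
    "Aurelia aurita": (26542, 27330, 109),
    "Cyanea capillata": (11838, 11838, 26),
    "Gadus morhua": (7725, 8141, 210),
    "Fish unspecified": (3310, 6163, 215),
    "Clupeidae": (1846, 5001, 335),
    "Jellyfish unspecified": (2160, 2262, 12),
    "Salmonidae": (599, 1479, 23),
    "Scomber scombrus": (133, 964, 53),
    "Pleuronectoidei": (921, 921, 12),
}

# Per-class (train images, val images, train boxes, val boxes) of the
# reference train/validation split.
REFERENCE_SPLIT = {
    "Ctenophora": (17412, 3283, 24297, 4503),
    "Aurelia aurita": (22486, 4056, 23131, 4199),
    "Cyanea capillata": (9414, 2424, 9414, 2424),
    "Gadus morhua": (6255, 1470, 6617, 1524),
    "Fish unspecified": (2564, 746, 4864, 1299),
    "Clupeidae": (1001, 845, 3588, 1413),
    "Jellyfish unspecified": (1836, 324, 1918, 344),
    "Salmonidae": (452, 147, 1192, 287),
    "Scomber scombrus": (116, 17, 863, 101),
    "Pleuronectoidei": (774, 147, 774, 147),
}


@dataclass
class TrackAnnotation:
    """All boxes of one animal over its visibility span."""

    track_id: int
    label: str
    frames: list            # strictly increasing frame indices
    boxes: list             # BoundingBox per frame
    image_ids: list         # image identifier per frame
    day: str | None = None  # recording-day metadata (for holdout splits)

    def __post_init__(self) -> None:
        if not self.boxes:
            raise ValueError("track must contain at least one box")
        if any(b >= a for a, b in zip(self.frames[1:], self.frames)):
            raise ValueError("track frames must be strictly increasing")

    @property
    def n_boxes(self) -> int:
        return len(self.boxes)


@dataclass
class ManifestSummary:
    """Per-class image/box/track counts with totals."""

    per_class: pd.DataFrame  # index: class; columns: images, boxes, tracks
    total_images: int
    total_boxes: int
    total_tracks: int


def read_annotations(path) -> list:
    """Read a VIAME-style CSV into TrackAnnotation objects.

    Expected columns per row: track id, image id, frame, TL_x, TL_y, BR_x,
    BR_y, detection confidence, target length, class[, class confidence].
    Lines starting with '#' are comments. Malformed rows and duplicate
    (track, frame) pairs raise with the offending line number.
    """
    tracks: dict = {}
    seen: set = set()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p.strip() for p in line.split(",")]
        if len(parts) < 10:
            raise ValueError(f"line {lineno}: expected >= 10 fields, got {len(parts)}")
        try:
            tid = int(parts[0])
            image_id = parts[1]
            frame = int(parts[2])
            x1, y1, x2, y2 = map(float, parts[3:7])
            label = parts[9]
        except (ValueError, IndexError) as exc:
            raise ValueError(f"line {lineno}: malformed row ({exc})") from exc
        if (tid, frame) in seen:
            raise ValueError(f"line {lineno}: duplicate (track {tid}, frame {frame})")
        seen.add((tid, frame))
        try:
            box = BoundingBox(x1, y1, x2, y2)
        except ValueError as exc:
            raise ValueError(f"line {lineno}: {exc}") from exc
        day = image_id.split("/")[0] if "/" in image_id else None
        rec = tracks.setdefault(tid, {"label": label, "rows": [], "day": day})
        rec["rows"].append((frame, box, image_id))
    out = []
    for tid in sorted(tracks):
        rec = tracks[tid]
        rows = sorted(rec["rows"])
        out.append(TrackAnnotation(track_id=tid, label=rec["label"],
                                   frames=[r[0] for r in rows],
                                   boxes=[r[1] for r in rows],
                                   image_ids=[r[2] for r in rows],
                                   day=rec["day"]))
    return out


def write_annotations(annotations, path) -> None:
    """Write TrackAnnotations back to VIAME-style CSV (round-trip safe)."""
    lines = ["# 1: Detection or Track-id, 2: Image Identifier, "
             "3: Unique Frame Identifier, 4-7: Img-bbox(TL_x,TL_y,BR_x,BR_y), "
             "8: Detection confidence, 9: Target Length, 10: Class"]
    for tr in annotations:
        for frame, box, image_id in zip(tr.frames, tr.boxes, tr.image_ids):
            lines.append(f"{tr.track_id},{image_id},{frame},"
                         f"{box.x1:g},{box.y1:g},{box.x2:g},{box.y2:g},"
                         f"1.0,-1,{tr.label}")
    Path(path).write_text("\n".join(lines) + "\n")


def summarize(annotations) -> ManifestSummary:
    """Per-class image, box and track counts over a set of annotations.

    An image counts toward a class when it contains at least one box of that
    class; the image total counts distinct images (which may host several
    classes), so it can be below the per-class sum.
    """
    annotations = list(annotations)
    if not annotations:
        raise ValueError("no annotations")
    per_class: dict = {}
    images_of_class: dict = {}
    all_images: set = set()
    for tr in annotations:
        rec = per_class.setdefault(tr.label, {"boxes": 0, "tracks": 0})
        rec["boxes"] += tr.n_boxes
        rec["tracks"] += 1
        images_of_class.setdefault(tr.label, set()).update(tr.image_ids)
        all_images.update(tr.image_ids)
    df = pd.DataFrame({
        "images": {c: len(images_of_class[c]) for c in per_class},
        "boxes": {c: per_class[c]["boxes"] for c in per_class},
        "tracks": {c: per_class[c]["tracks"] for c in per_class},
    }).sort_index()
    return ManifestSummary(per_class=df, total_images=len(all_images),
                           total_boxes=int(df["boxes"].sum()),
                           total_tracks=int(df["tracks"].sum()))


def summary_from_class_rows(rows: dict) -> dict:
    """Totals from printed per-class manifest rows.

    ``rows`` maps class -> tuple of counts (e.g. images, boxes, tracks);
    returns the column-wise totals as a tuple. Image totals computed this
    way are upper bounds, since images may host multiple classes.
    """
    arr = np.array(list(rows.values()), dtype=int)
    return tuple(int(x) for x in arr.sum(axis=0))


def images_from_annotations(annotations, background_images=()) -> pd.DataFrame:
    """Distinct images with day metadata and box counts.

    ``background_images`` adds annotation-free images (id or (id, day)) as
    first-class entries so a split can include negatives.
    """
    counts: dict = {}
    days: dict = {}
    for tr in annotations:
        for image_id in tr.image_ids:
            counts[image_id] = counts.get(image_id, 0) + 1
            days.setdefault(image_id, tr.day)
    for entry in background_images:
        image_id, day = entry if isinstance(entry, tuple) else (entry, None)
        counts.setdefault(image_id, 0)
        days.setdefault(image_id, day)
    ids = sorted(counts)
    return pd.DataFrame({"image_id": ids,
                         "day": [days[i] for i in ids],
                         "n_boxes": [counts[i] for i in ids]})


def split(images: pd.DataFrame, ratio: float = 0.85, seed: int = 0,
          holdout_days=()) -> tuple:
    """Per-image train/validation split with hard-day holdout.

    ``images`` as returned by :func:`images_from_annotations`. All images of
    a holdout day go to validation; the training set is then filled by
    random per-image sampling from the remainder up to ``round(ratio * N)``.
    Returns ``(train_ids, val_ids)`` as sorted lists; deterministic given
    the seed.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must lie in (0, 1)")
    ids = list(images["image_id"])
    days = dict(zip(images["image_id"], images["day"]))
    holdout = set(holdout_days)
    forced_val = [i for i in ids if days.get(i) in holdout]
    pool = [i for i in ids if days.get(i) not in holdout]
    n_train = round(ratio * len(ids))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(pool))
    train = {pool[k] for k in perm[:min(n_train, len(pool))]}
    val = set(forced_val) | {pool[k] for k in perm[min(n_train, len(pool)):]}
    return sorted(train), sorted(val)
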
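"""MaxN relative-abundance estimation over activity sequences.

MaxN is the maximum number of individuals of a species visible in any single
frame of an observation period — a deliberately conservative sampling regime
that can never double-count within a sequence (at the cost of undercounting
groups that pass through gradually). Sequence-level MaxN values are then
aggregated over configurable time intervals (per hour, per day, or fixed
frame blocks); an animal re-entering the scene in a later activity sequence
is counted anew, since no individual re-identification is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .activity import ActivitySequence

__all__ = ["AbundanceRecord", "per_frame_counts", "maxn", "aggregate",
           "records_to_frame"]


@dataclass(frozen=True)
class AbundanceRecord:
    """MaxN of one species within one activity sequence (or interval)."""

    species: str
    maxn: int
    start_frame: int
    end_frame: int
    argmax_frame: int
    sequence_id: str = "stream0"
    start_time_s: float | None = None

    def __post_init__(self) -> None:
        if self.maxn < 0:
            raise ValueError("maxn must be non-negative")
        if self.start_frame > self.end_frame:
            raise ValueError("interval must be well-ordered")


def per_frame_counts(detections, sequence: ActivitySequence,
                     camera: str = "left") -> pd.DataFrame:
    """Per-frame per-species detection counts within a sequence's span.

    Expects confidence-filtered, NMS-applied detections. Returns a DataFrame
    indexed by frame (the full, zero-filled span) with one column per
    species observed.
    """
    frames = range(sequence.start, sequence.end + 1)
    dets = [d for d in detections
            if d.camera == camera and sequence.start <= d.frame <= sequence.end]
    species = sorted({d.label for d in dets})
    counts = pd.DataFrame(0, index=pd.Index(frames, name="frame"),
                          columns=species, dtype=int)
    for d in dets:
        counts.loc[d.frame, d.label] += 1
    return counts


def maxn(counts: pd.DataFrame, sequence: ActivitySequence) -> list:
    """Per-species MaxN over one sequence, with the earliest argmax frame."""
    records = []
    for species in counts.columns:
        col = counts[species]
        m = int(col.max()) if len(col) else 0
        if m <= 0:
            continue
        arg = int(col.index[np.argmax(col.values)])  # first maximum
        records.append(AbundanceRecord(species=species, maxn=m,
                                       start_frame=sequence.start,
                                       end_frame=sequence.end,
                                       argmax_frame=arg,
                                       sequence_id=sequence.stream_id))
    return records


def sequence_maxn(detections, sequence: ActivitySequence,
                  camera: str = "left") -> list:
    """Convenience: counts + MaxN for one sequence."""
    return maxn(per_frame_counts(detections, sequence, camera), sequence)


def aggregate(records, interval="hour", fps: float = 20.0,
              epoch_s: float = 0.0) -> pd.DataFrame:
    """Sum sequence-level MaxN values over time intervals.

    ``interval`` is ``"hour"``, ``"day"`` or an integer number of frames.
    A sequence belongs to the interval containing its *start* frame; each
    sequence contributes its full MaxN (re-entering animals count anew).
    Timestamps are derived as ``epoch_s + frame / fps`` unless records carry
    ``start_time_s``. Returns a DataFrame with columns interval_start,
    interval_end, species, maxn_sum, n_sequences.

    Raises ``ValueError`` when a time-based interval is requested but no
    frame rate is available.
    """
    records = list(records)
    if isinstance(interval, str):
        if interval not in ("hour", "day"):
            raise ValueError("interval must be 'hour', 'day' or a frame count")
        if fps is None or fps <= 0:
            raise ValueError("time-based aggregation requires a frame rate")
        span_s = 3600.0 if interval == "hour" else 86400.0

        def key(r):
            t = r.start_time_s if r.start_time_s is not None \
                else epoch_s + r.start_frame / fps
            return int(t // span_s)

        def bounds(k):
            return k * span_s, (k + 1) * span_s
    else:
        span_f = int(interval)
        if span_f <= 0:
            raise ValueError("frame interval must be positive")

        def key(r):
            return r.start_frame // span_f

        def bounds(k):
            return k * span_f, (k + 1) * span_f

    rows: dict = {}
    for r in records:
        k = (key(r), r.species)
        if k not in rows:
            rows[k] = {"maxn_sum": 0, "n_sequences": 0}
        rows[k]["maxn_sum"] += r.maxn
        rows[k]["n_sequences"] += 1
    out = []
    for (k, species), v in sorted(rows.items()):
        lo, hi = bounds(k)
        out.append({"interval_start": lo, "interval_end": hi,
                    "species": species, **v})
    return pd.DataFrame(out, columns=["interval_start", "interval_end",
                                      "species", "maxn_sum", "n_sequences"])


def records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])
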
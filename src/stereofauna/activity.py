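"""Activity detection by adaptive Gaussian-mixture background subtraction.

Continuous observatory video is mostly empty water; this stage reduces it to
*activity sequences* — contiguous frame intervals containing motion — so that
downstream detection only runs on candidate material. Each pixel's intensity
history is modelled online by a mixture of up to K Gaussians (in the adaptive
style of Zivkovic's background-subtraction scheme): components compete via
their mixing weights, heavy components form the background model, and a
median-prefiltered pixel whose intensity lies beyond the variance gate of
every background component is declared foreground.

The stage is deliberately tuned for recall, not precision: its job is to
never miss an animal, while false alarms only cost downstream compute. It is
optional in an online pipeline where the detector itself is fast enough.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter

__all__ = ["ActivityParams", "ActivitySequence", "BackgroundModel",
           "foreground_fraction", "extract_sequences"]


@dataclass(frozen=True)
class ActivityParams:
    """Hyperparameters of the background model and sequence extraction.

    median_kernel : odd spatial size of the median prefilter (px).
    history : frames over which the model adapts; learning rate is 1/history
        unless ``learning_rate`` is given.
    n_components : maximum Gaussians per pixel.
    var_threshold : squared-Mahalanobis gate; a pixel matches a component
        when (x - mu)^2 < var_threshold * var.
    background_ratio : cumulative weight mass treated as background.
    fraction_threshold : foreground pixel fraction above which a frame is
        considered active.
    min_length : minimum sequence length (frames).
    merge_gap : inactive gaps up to this many frames are bridged.
    """

    median_kernel: int = 5
    history: int = 100
    n_components: int = 5
    var_threshold: float = 16.0
    learning_rate: float | None = None
    background_ratio: float = 0.9
    init_variance: float = 225.0
    min_variance: float = 4.0
    fraction_threshold: float = 0.001
    min_length: int = 5
    merge_gap: int = 10

    def __post_init__(self) -> None:
        if self.median_kernel < 1 or self.median_kernel % 2 == 0:
            raise ValueError("median kernel must be odd and >= 1")
        if not 0.0 < (self.learning_rate or 1.0 / self.history) <= 1.0:
            raise ValueError("learning rate must lie in (0, 1]")
        if not 0.0 < self.fraction_threshold < 1.0:
            raise ValueError("fraction threshold must lie in (0, 1)")

    @property
    def alpha(self) -> float:
        return self.learning_rate if self.learning_rate is not None else 1.0 / self.history


@dataclass
class ActivitySequence:
    """A contiguous interval of active frames (inclusive bounds)."""

    start: int
    end: int
    fractions: np.ndarray  # per-frame foreground fraction over [start, end]
    stream_id: str = "stream0"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("start must not exceed end")

    @property
    def n_frames(self) -> int:
        return self.end - self.start + 1

    @property
    def mean_fraction(self) -> float:
        return float(np.mean(self.fractions))


class BackgroundModel:
    """Online per-pixel Gaussian mixture over grayscale intensity."""

    def __init__(self, shape, params: ActivityParams):
        K = params.n_components
        self.params = params
        self.mu = np.zeros((K,) + tuple(shape))
        self.var = np.full((K,) + tuple(shape), params.init_variance)
        self.w = np.zeros((K,) + tuple(shape))
        self._initialized = False

    def apply(self, frame: np.ndarray) -> np.ndarray:
        """Classify one (median-filtered) frame and update the model.

        Returns the boolean foreground mask.
        """
        p = self.params
        x = frame.astype(float)
        if not self._initialized:
            self.mu[0] = x
            self.w[0] = 1.0
            self._initialized = True
            return np.zeros(x.shape, dtype=bool)

        d2 = (x[None] - self.mu) ** 2
        matched = d2 < p.var_threshold * self.var

        # Background components: heaviest components whose cumulative weight
        # stays within background_ratio. A pixel is foreground when it
        # matches none of them.
        order = np.argsort(-self.w, axis=0, kind="stable")
        w_sorted = np.take_along_axis(self.w, order, axis=0)
        cum = np.cumsum(w_sorted, axis=0)
        is_bg_sorted = (cum - w_sorted) < p.background_ratio
        is_bg = np.zeros_like(matched)
        np.put_along_axis(is_bg, order, is_bg_sorted, axis=0)
        foreground = ~np.any(matched & is_bg, axis=0)

        # Update: ownership goes to the best (heaviest) matching component.
        any_match = np.any(matched, axis=0)
        w_masked = np.where(matched, self.w, -1.0)
        best = np.argmax(w_masked, axis=0)
        K = self.w.shape[0]
        own = (np.arange(K)[:, None, None] == best[None]) & any_match[None]
        alpha = p.alpha
        self.w += alpha * (own.astype(float) - self.w)
        rho = alpha / np.maximum(self.w, alpha)
        upd = own
        self.mu = np.where(upd, self.mu + rho * (x[None] - self.mu), self.mu)
        self.var = np.where(upd, self.var + rho * (d2 - self.var), self.var)
        self.var = np.clip(self.var, p.min_variance, None)

        # No match: replace the lightest component with a fresh Gaussian.
        if np.any(~any_match):
            lightest = np.argmin(self.w, axis=0)
            repl = (np.arange(K)[:, None, None] == lightest[None]) & (~any_match)[None]
            self.mu = np.where(repl, x[None], self.mu)
            self.var = np.where(repl, p.init_variance, self.var)
            self.w = np.where(repl, alpha, self.w)
        self.w /= np.sum(self.w, axis=0, keepdims=True)
        return foreground


def foreground_fraction(frames, params: ActivityParams | None = None) -> np.ndarray:
    """Per-frame foreground pixel fraction of a grayscale frame sequence.

    ``frames`` is an iterable of 2D arrays (or an (n, h, w) array). Each
    frame is median filtered before entering the background model.

    Raises ``ValueError`` on an empty stream.
    """
    params = params or ActivityParams()
    model = None
    fractions = []
    for frame in frames:
        f = np.asarray(frame)
        if f.ndim != 2:
            raise ValueError("frames must be 2D grayscale")
        if params.median_kernel > 1:
            f = median_filter(f, size=params.median_kernel)
        if model is None:
            model = BackgroundModel(f.shape, params)
        mask = model.apply(f)
        fractions.append(mask.mean())
    if model is None:
        raise ValueError("empty frame stream")
    return np.asarray(fractions)


def extract_sequences(fractions, params: ActivityParams | None = None,
                      stream_id: str = "stream0") -> list:
    """Turn a foreground-fraction series into activity sequences.

    Frames with fraction >= ``fraction_threshold`` are active; runs of
    active frames separated by at most ``merge_gap`` inactive frames are
    joined; runs shorter than ``min_length`` are discarded. The result is
    sorted and non-overlapping.
    """
    params = params or ActivityParams()
    fr = np.asarray(fractions, dtype=float)
    if fr.size == 0:
        raise ValueError("empty fraction series")
    active = fr >= params.fraction_threshold
    runs = []
    start = None
    for i, a in enumerate(active):
        if a and start is None:
            start = i
        elif not a and start is not None:
            runs.append([start, i - 1])
            start = None
    if start is not None:
        runs.append([start, len(active) - 1])
    merged = []
    for run in runs:
        if merged and run[0] - merged[-1][1] - 1 <= params.merge_gap:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    return [ActivitySequence(s, e, fr[s:e + 1], stream_id)
            for s, e in merged if e - s + 1 >= params.min_length]
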
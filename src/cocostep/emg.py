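"""EMG linear envelopes: filter chain, grand-mean normalization, epoching.

The envelope chain is, in order: resample to 1 kHz, band-pass 30–200 Hz,
full-wave rectify, low-pass 20 Hz — all filters designed as 6th-order
Butterworth and applied forward–backward (zero phase), since offline
analysis tolerates no 200-ms-scale group delay near event-locked
integrals.  The 20 Hz low-pass is wide enough to keep envelope
fluctuations at the 200-ms perturbation time scale.

Envelopes are normalized per channel to the grand mean of that channel's
envelope pooled across all of a subject's tasks (not to maximal voluntary
contraction), and per-stride epochs are time-normalized to a fixed grid
anchored at the four stride events.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal
from sklearn.base import BaseEstimator, TransformerMixin

from .kinematics import Stride


class FilterError(ValueError):
    """Signal too short for the envelope filter chain."""


class DeadChannelError(ValueError):
    """A channel's grand-mean envelope is zero; it cannot be normalized."""


class EpochingError(ValueError):
    """A stride event falls outside the envelope's time span."""


class LinearEnvelope(BaseEstimator, TransformerMixin):
    """Raw EMG to linear envelope, as a stateless sklearn transformer.

    Parameters
    ----------
    in_rate : float
        Measured input sampling rate in Hz (~1.1 kHz for wireless
        sensors; the true device rate, not the nominal one, should be
        passed so the polyphase resampler lands exactly on ``out_rate``).
    out_rate : float
        Output envelope rate, default 1000 Hz.
    band : (float, float)
        Band-pass corner frequencies in Hz.
    lowpass : float
        Envelope smoothing corner in Hz.
    order : int
        Butterworth design order of each filter.  Filters run
        forward–backward, which doubles the effective attenuation.
    """

    def __init__(self, in_rate: float, out_rate: float = 1000.0,
                 band: tuple[float, float] = (30.0, 200.0),
                 lowpass: float = 20.0, order: int = 6):
        self.in_rate = in_rate
        self.out_rate = out_rate
        self.band = band
        self.lowpass = lowpass
        self.order = order

    def fit(self, X=None, y=None) -> "LinearEnvelope":
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Apply resample -> band-pass -> rectify -> low-pass.

        ``X`` is 1-D (one channel) or 2-D ``(n_samples, n_channels)``;
        the output is at ``out_rate`` and nonnegative.
        """
        x = np.asarray(X, dtype=float)
        squeeze = x.ndim == 1
        if squeeze:
            x = x[:, None]
        if x.shape[0] < self.in_rate:
            raise FilterError(
                f"signal of {x.shape[0]} samples ({x.shape[0] / self.in_rate:.2f} s) "
                "is shorter than the 1 s filter warm-up")
        ratio = Fraction(self.out_rate / self.in_rate).limit_denominator(10000)
        y = signal.resample_poly(x, ratio.numerator, ratio.denominator, axis=0)
        sos_bp = signal.butter(self.order, self.band, btype="bandpass",
                               fs=self.out_rate, output="sos")
        y = signal.sosfiltfilt(sos_bp, y, axis=0)
        y = np.abs(y)
        sos_lp = signal.butter(self.order, self.lowpass, btype="lowpass",
                               fs=self.out_rate, output="sos")
        y = signal.sosfiltfilt(sos_lp, y, axis=0)
        y = np.clip(y, 0.0, None)  # filtfilt undershoot of the rectified signal
        return y[:, 0] if squeeze else y


def compute_linear_envelope(x: np.ndarray, in_rate: float, **params) -> np.ndarray:
    """Functional wrapper over :class:`LinearEnvelope`."""
    return LinearEnvelope(in_rate=in_rate, **params).transform(x)


class EnvelopeNormalizer(BaseEstimator, TransformerMixin):
    """Divide each channel by its grand-mean envelope across all tasks.

    ``fit`` accepts a single envelope matrix or a list of per-task
    matrices (``(n_samples, n_channels)`` each, channels aligned); the
    per-channel mean is pooled over the concatenation, so after
    transforming all tasks each channel's pooled mean is exactly 1.

    Attributes
    ----------
    norm_ : ndarray of shape (n_channels,)
        Per-channel grand-mean envelope (the normalization constants).
    """

    def __init__(self, labels: Sequence[str] | None = None):
        self.labels = labels

    def fit(self, X, y=None) -> "EnvelopeNormalizer":
        tasks = X if isinstance(X, (list, tuple)) else [X]
        stacked = np.concatenate([np.atleast_2d(np.asarray(a, dtype=float).T).T
                                  for a in tasks], axis=0)
        norm = stacked.mean(axis=0)
        dead = np.flatnonzero(norm <= 0)
        if len(dead):
            names = ([str(self.labels[i]) for i in dead] if self.labels is not None
                     else [f"channel {i}" for i in dead])
            raise DeadChannelError(
                f"dead channel(s) with zero grand-mean envelope: {', '.join(names)}")
        self.norm_ = norm
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) / self.norm_


@dataclass
class EnvelopeSet:
    """Normalized per-channel envelopes on a common clock."""

    time: np.ndarray
    envelopes: pd.DataFrame      # columns = channel labels, normalized
    norms: pd.Series             # per-channel grand-mean constants
    rate: float = 1000.0


def normalize_envelopes(
    tasks: Sequence[pd.DataFrame],
    times: Sequence[np.ndarray],
    rate: float = 1000.0,
) -> list[EnvelopeSet]:
    """Normalize a subject's per-task envelope frames jointly.

    All tasks share one set of per-channel constants (the grand mean over
    the pooled tasks), as required for cross-task comparability.
    """
    if len(tasks) == 0:
        raise ValueError("need at least one task")
    labels = list(tasks[0].columns)
    for frame in tasks[1:]:
        if list(frame.columns) != labels:
            raise ValueError("all tasks must share the same channel labels")
    normalizer = EnvelopeNormalizer(labels=labels)
    normalizer.fit([frame.to_numpy() for frame in tasks])
    norms = pd.Series(normalizer.norm_, index=labels)
    return [
        EnvelopeSet(
            time=np.asarray(t),
            envelopes=pd.DataFrame(normalizer.transform(frame.to_numpy()),
                                   columns=labels),
            norms=norms,
            rate=rate,
        )
        for frame, t in zip(tasks, times)
    ]


#: Samples per epoch segment: onset->perturbation, perturbation->contra
#: onset, contra onset->end.  Resolution is proportional to typical
#: segment durations; the closing endpoint brings the grid to 101.
EPOCH_SEGMENTS = (25, 25, 50)


def epoch_grid_size(segments: tuple[int, int, int] = EPOCH_SEGMENTS) -> int:
    return sum(segments) + 1


def epoch_time_normalize(
    envelope_set: EnvelopeSet,
    strides: Sequence[Stride],
    segments: tuple[int, int, int] = EPOCH_SEGMENTS,
) -> np.ndarray:
    """Event-anchored, time-normalized per-stride epochs.

    Each complete stride's envelopes are mapped onto a fixed grid by
    piecewise-linear time warping anchored at the four events (onset,
    perturbation, contralateral onset, end) with ``segments`` samples per
    segment.  A zero-length first segment (extension-onset tasks trigger
    at the onset itself) fills with the boundary value.  Returns an array
    of shape ``(n_strides, grid_size, n_channels)``.
    """
    t = envelope_set.time
    values = envelope_set.envelopes.to_numpy()
    used = [s for s in strides if s.complete]
    n_grid = epoch_grid_size(segments)
    out = np.empty((len(used), n_grid, values.shape[1]))
    for i, stride in enumerate(used):
        anchors = (stride.onset_time, stride.perturbation_time,
                   stride.contra_onset_time, stride.end_time)
        if anchors[0] < t[0] or anchors[-1] > t[-1]:
            raise EpochingError(
                f"stride {stride.index} events [{anchors[0]:.2f}, "
                f"{anchors[-1]:.2f}] s outside envelope span "
                f"[{t[0]:.2f}, {t[-1]:.2f}] s")
        if not (anchors[0] <= anchors[1] <= anchors[2] <= anchors[3]):
            raise EpochingError(
                f"stride {stride.index} events are out of order: {anchors}")
        sample_times = np.concatenate([
            np.linspace(anchors[j], anchors[j + 1], segments[j],
                        endpoint=False)
            for j in range(3)
        ] + [[anchors[3]]])
        for c in range(values.shape[1]):
            out[i, :, c] = np.interp(sample_times, t, values[:, c])
    return out


def epochs_to_frame(
    epochs: np.ndarray,
    strides: Sequence[Stride],
    labels: Sequence[str],
) -> pd.DataFrame:
    """Long-format epoch table: stride_idx, channel, grid_idx, value."""
    used = [s for s in strides if s.complete]
    if epochs.shape[0] != len(used):
        raise ValueError("epochs and complete strides are misaligned")
    n_strides, n_grid, n_channels = epochs.shape
    stride_idx = np.repeat([s.index for s in used], n_grid * n_channels)
    grid_idx = np.tile(np.repeat(np.arange(n_grid), n_channels), n_strides)
    channel = np.tile(list(labels), n_strides * n_grid)
    return pd.DataFrame({
        "stride_idx": stride_idx,
        "channel": channel,
        "grid_idx": grid_idx,
        "value": epochs.reshape(-1),
    })
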
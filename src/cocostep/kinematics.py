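"""Stride segmentation and in-stride event detection for stepper traces.

A stride runs from one extension onset of the perturbed leg to the next,
and carries four events: the perturbed-leg extension onset, the
perturbation start time (real for perturbed strides, virtual for pre,
post and catch strides), the unperturbed-leg extension onset, and the
stride end.  Extension onsets are turning points of the single-axis
stepper angle: the angle increases during left-limb extension, so
left-leg extension onsets are minima and right-leg onsets are maxima.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal
from sklearn.base import BaseEstimator

from .synth import ProtocolConfig, StepperTrace


class SegmentationError(ValueError):
    """The trace cannot be segmented into strides."""


class DataIntegrityError(ValueError):
    """Logged perturbation commands are inconsistent with the strides."""


@dataclass
class Stride:
    """One stride with its four events and task flags.

    Times are seconds from trace start; intervals are half-open
    ``[onset, end)``.  ``perturbation_time`` may coincide with the onset
    (extension-onset tasks trigger at zero latency).
    """

    index: int
    onset_time: float
    end_time: float | None = None
    contra_onset_time: float | None = None
    perturbation_time: float | None = None
    block: str = "unknown"
    is_catch: bool = False
    is_perturbed: bool = False
    virtual_perturbation: bool = False

    @property
    def complete(self) -> bool:
        """True when all four events are present and correctly ordered."""
        if self.end_time is None or self.contra_onset_time is None:
            return False
        if self.perturbation_time is None:
            return False
        return (
            self.onset_time < self.contra_onset_time < self.end_time
            and self.onset_time <= self.perturbation_time < self.end_time
        )

    @property
    def duration(self) -> float:
        if self.end_time is None:
            return math.nan
        return self.end_time - self.onset_time

    @property
    def latency(self) -> float:
        """Perturbation latency from stride onset (NaN when unset)."""
        if self.perturbation_time is None:
            return math.nan
        return self.perturbation_time - self.onset_time


def strides_to_frame(strides: Iterable[Stride]) -> pd.DataFrame:
    """Tidy events table (one row per stride)."""
    rows = [
        {
            "stride_idx": s.index,
            "block": s.block,
            "is_catch": s.is_catch,
            "is_perturbed": s.is_perturbed,
            "onset_s": s.onset_time,
            "perturb_s": s.perturbation_time,
            "virtual_flag": s.virtual_perturbation,
            "contra_onset_s": s.contra_onset_time,
            "end_s": s.end_time,
            "complete": s.complete,
        }
        for s in strides
    ]
    return pd.DataFrame(rows)


def frame_to_strides(frame: pd.DataFrame) -> list[Stride]:
    """Inverse of :func:`strides_to_frame`."""
    out = []
    for _, r in frame.iterrows():
        out.append(Stride(
            index=int(r["stride_idx"]),
            onset_time=float(r["onset_s"]),
            end_time=None if pd.isna(r["end_s"]) else float(r["end_s"]),
            contra_onset_time=(None if pd.isna(r["contra_onset_s"])
                               else float(r["contra_onset_s"])),
            perturbation_time=(None if pd.isna(r["perturb_s"])
                               else float(r["perturb_s"])),
            block=str(r["block"]),
            is_catch=bool(r["is_catch"]),
            is_perturbed=bool(r["is_perturbed"]),
            virtual_perturbation=bool(r.get("virtual_flag", False)),
        ))
    return out


class StrideSegmenter(BaseEstimator):
    """Detect stride events from a stepper-angle trace.

    The angle is low-pass filtered (``smooth_cutoff`` Hz, zero-phase
    Butterworth) before turning points are located, extrema closer than
    ``min_separation_strides`` nominal strides to a same-type neighbour
    are rejected, and event times are refined to sub-sample precision by
    parabolic interpolation of the filtered angle — the 10-ms kinematic
    sampling grid is coarse relative to 50-ms effects of interest.

    Parameters
    ----------
    smooth_cutoff : float
        Low-pass corner frequency (Hz) applied before differentiation.
    smooth_order : int
        Butterworth design order of the smoothing filter.
    min_separation_strides : float
        Minimum distance between same-type turning points, in nominal
        strides.
    min_prominence_frac : float
        Minimum extremum prominence as a fraction of the trace's angular
        range; rejects small perturbation-induced wiggles.
    nominal_stride : float
        Nominal stride duration in s (2 s at 60 steps/min pacing).

    Attributes
    ----------
    strides_ : list of Stride
        Detected strides in time order (set by :meth:`fit`).
    onset_times_, contra_times_ : ndarray
        Refined turning-point times for the perturbed and unperturbed leg.
    """

    def __init__(self, smooth_cutoff: float = 6.0, smooth_order: int = 4,
                 min_separation_strides: float = 0.5,
                 min_prominence_frac: float = 0.25,
                 nominal_stride: float = 2.0):
        self.smooth_cutoff = smooth_cutoff
        self.smooth_order = smooth_order
        self.min_separation_strides = min_separation_strides
        self.min_prominence_frac = min_prominence_frac
        self.nominal_stride = nominal_stride

    def fit(self, trace: StepperTrace, y=None) -> "StrideSegmenter":
        """Segment ``trace`` into strides; populates ``strides_``."""
        t, angle = self._validate(trace)
        fs = trace.rate
        sos = signal.butter(self.smooth_order, self.smooth_cutoff,
                            btype="lowpass", fs=fs, output="sos")
        smooth = signal.sosfiltfilt(sos, angle)

        dist = max(1, int(self.min_separation_strides * self.nominal_stride * fs))
        prominence = self.min_prominence_frac * np.ptp(smooth)
        maxima, _ = signal.find_peaks(smooth, distance=dist, prominence=prominence)
        minima, _ = signal.find_peaks(-smooth, distance=dist, prominence=prominence)
        if len(maxima) + len(minima) < 3:
            raise SegmentationError(
                "trace is not oscillatory: found "
                f"{len(maxima)} maxima and {len(minima)} minima "
                f"(angular range {np.ptp(angle):.2f} deg)")

        # left extension onset = minimum of the angle, right = maximum
        if trace.perturbed_side == "left":
            onset_idx, contra_idx = minima, maxima
        else:
            onset_idx, contra_idx = maxima, minima
        onsets = _refine_extrema(t, smooth, onset_idx)
        contras = _refine_extrema(t, smooth, contra_idx)
        if len(onsets) < 2:
            raise SegmentationError(
                f"found only {len(onsets)} perturbed-leg extension onsets; "
                "need at least 2 to form a stride")

        blocks = trace.block_bounds or {}
        strides: list[Stride] = []
        for k, onset in enumerate(onsets):
            end = onsets[k + 1] if k + 1 < len(onsets) else None
            inside = (contras[(contras > onset) & (contras < end)]
                      if end is not None else np.empty(0))
            contra = float(inside[0]) if len(inside) == 1 else None
            # classify by the stride midpoint: onsets can jitter by a few
            # ms around a block boundary, midpoints cannot
            anchor = onset if end is None else 0.5 * (onset + end)
            strides.append(Stride(
                index=k,
                onset_time=float(onset),
                end_time=None if end is None else float(end),
                contra_onset_time=contra,
                block=_block_of(anchor, blocks),
            ))
        self.onset_times_ = onsets
        self.contra_times_ = contras
        self.strides_ = strides
        return self

    def _validate(self, trace: StepperTrace) -> tuple[np.ndarray, np.ndarray]:
        t = np.asarray(trace.time, dtype=float)
        angle = np.asarray(trace.angle, dtype=float)
        if t.ndim != 1 or t.shape != angle.shape:
            raise SegmentationError("time and angle must be 1-D and aligned")
        dt = np.diff(t)
        if len(dt) == 0 or np.any(dt <= 0):
            raise SegmentationError("time must be strictly increasing")
        if np.ptp(dt) > 0.01 * np.median(dt):
            raise SegmentationError("trace is not uniformly sampled")
        measured_rate = 1.0 / np.median(dt)
        if abs(measured_rate - trace.rate) > 0.01 * trace.rate:
            raise SegmentationError(
                f"sample rate {measured_rate:.2f} Hz deviates more than 1% "
                f"from nominal {trace.rate:.2f} Hz")
        if t[-1] - t[0] < 2 * self.nominal_stride:
            raise SegmentationError(
                f"trace of {t[-1] - t[0]:.2f} s is shorter than two nominal "
                f"strides ({2 * self.nominal_stride:.2f} s)")
        return t, angle


def _refine_extrema(t: np.ndarray, y: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Parabolic sub-sample refinement of extrema sample indices."""
    out = np.empty(len(idx))
    dt = t[1] - t[0]
    for j, i in enumerate(idx):
        if 0 < i < len(y) - 1:
            denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
            shift = 0.0 if denom == 0 else 0.5 * (y[i - 1] - y[i + 1]) / denom
            out[j] = t[i] + np.clip(shift, -1.0, 1.0) * dt
        else:
            out[j] = t[i]
    return out


def _block_of(time: float, blocks: dict[str, tuple[float, float]]) -> str:
    for name, (start, end) in blocks.items():
        if start <= time < end:
            return name
    return "unknown"


def detect_stride_events(
    trace: StepperTrace,
    perturbed_side: str | None = None,
    **segmenter_params,
) -> list[Stride]:
    """Functional wrapper over :class:`StrideSegmenter`.

    ``perturbed_side`` overrides the side stored on the trace.  The
    nominal stride duration is taken from the trace's protocol config
    when available.
    """
    if perturbed_side is not None and perturbed_side != trace.perturbed_side:
        trace = StepperTrace(
            time=trace.time, angle=trace.angle, rate=trace.rate,
            perturbed_side=perturbed_side,
            perturbation_window=trace.perturbation_window,
            block_bounds=trace.block_bounds, events=trace.events,
            config=trace.config)
    if trace.config is not None and "nominal_stride" not in segmenter_params:
        segmenter_params["nominal_stride"] = trace.config.stride_duration
    return StrideSegmenter(**segmenter_params).fit(trace).strides_


def assign_perturbation_events(
    strides: Sequence[Stride],
    command_times: Sequence[float],
    config: ProtocolConfig | None = None,
) -> list[Stride]:
    """Attach logged perturbation command times to the strides.

    Each perturbed-block stride receives the command time falling inside
    it (``[onset, end)``) and is flagged perturbed; perturbed-block
    strides without a command become catch strides.  Two commands inside
    one stride indicate a corrupted log and raise.  Strides outside the
    perturbed block are never altered.
    """
    commands = np.sort(np.asarray(list(command_times), dtype=float))
    for stride in strides:
        if stride.end_time is None:
            inside = commands[commands >= stride.onset_time]
        else:
            inside = commands[(commands >= stride.onset_time)
                              & (commands < stride.end_time)]
        if len(inside) > 1:
            raise DataIntegrityError(
                f"stride {stride.index} ([{stride.onset_time:.2f}, "
                f"{stride.end_time}) s) contains {len(inside)} perturbation "
                "commands; expected at most one")
        if stride.block != "perturbed":
            continue
        if len(inside) == 1:
            stride.perturbation_time = float(inside[0])
            stride.is_perturbed = True
            stride.is_catch = False
        else:
            stride.is_catch = True
            stride.is_perturbed = False
    return list(strides)


def insert_virtual_perturbation_events(strides: Sequence[Stride]) -> list[Stride]:
    """Give unperturbed strides a virtual perturbation event.

    Pre, post and catch strides receive ``onset + mean latency``, where
    the mean is taken over the real perturbation events of the task, so
    that event-anchored epoching treats all strides alike.
    """
    latencies = [s.latency for s in strides
                 if s.is_perturbed and s.perturbation_time is not None]
    if not latencies:
        raise DataIntegrityError(
            "no perturbed strides with real perturbation events in this task; "
            "cannot derive the virtual latency")
    mean_latency = float(np.mean(latencies))
    for stride in strides:
        if stride.is_perturbed:
            continue
        stride.perturbation_time = stride.onset_time + mean_latency
        stride.virtual_perturbation = True
    return list(strides)


def filter_incomplete_strides(
    strides: Sequence[Stride],
) -> tuple[list[Stride], int]:
    """Keep only strides carrying all four events; returns (kept, n_dropped)."""
    kept = [s for s in strides if s.complete]
    return kept, len(strides) - len(kept)
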
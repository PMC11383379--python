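"""Per-stride motor-error metrics: temporal and spatial error.

Temporal error is the signed difference between a stride's duration and
the pacing reference (2 s at 60 steps/min).  Spatial error is the maximum
absolute deviation of the stride's time-normalized angle profile from the
averaged preperturbation (baseline) profile, in degrees; it is invariant
to stride duration by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .kinematics import Stride
from .synth import StepperTrace


class BaselineError(ValueError):
    """Not enough clean pre-block strides to form a baseline profile."""


@dataclass
class BaselineProfile:
    """Mean pre-block stepping profile on a normalized-time grid."""

    grid: np.ndarray        # n_points on [0, 1]
    mean_angle: np.ndarray  # degrees
    n_strides: int
    task_side: str = ""


def reference_stride_duration(pacing_rate: float = 60.0) -> float:
    """Stride-reference duration: two steps at the pacing rate, in s."""
    if pacing_rate <= 0:
        raise ValueError(f"pacing_rate must be positive, got {pacing_rate}")
    return 2.0 * 60.0 / pacing_rate


def temporal_error(stride: Stride, pacing_rate: float = 60.0) -> float:
    """Signed stride-duration error: duration minus the pacing reference."""
    if not stride.complete:
        raise ValueError(
            f"stride {stride.index} is incomplete; temporal error undefined")
    return stride.duration - reference_stride_duration(pacing_rate)


def _resample_stride(
    stride: Stride, trace: StepperTrace, n_points: int
) -> np.ndarray:
    """Stride angle on a normalized-time grid of ``n_points``."""
    times = np.linspace(stride.onset_time, stride.end_time, n_points)
    return np.interp(times, trace.time, trace.angle)


def baseline_profile(
    pre_strides: Sequence[Stride],
    trace: StepperTrace,
    n_points: int = 101,
    skip_initial: int = 5,
) -> BaselineProfile:
    """Average time-normalized pre-block stepping profile.

    The first ``skip_initial`` pre strides are excluded as ramp-up (early
    strides are atypical even after familiarization); at least 5 complete
    strides must remain.  Each stride's angle is resampled to ``n_points``
    on normalized time [0, 1] (the percent-of-stride convention at the
    default 101) and averaged pointwise.
    """
    usable = [s for s in pre_strides if s.complete and s.block == "pre"]
    usable = usable[skip_initial:]
    if len(usable) < 5:
        raise BaselineError(
            f"only {len(usable)} complete pre strides after skipping "
            f"{skip_initial}; need at least 5 for a baseline")
    profiles = np.stack([_resample_stride(s, trace, n_points) for s in usable])
    return BaselineProfile(
        grid=np.linspace(0.0, 1.0, n_points),
        mean_angle=profiles.mean(axis=0),
        n_strides=len(usable),
        task_side=trace.perturbed_side,
    )


def spatial_error(
    stride: Stride, trace: StepperTrace, baseline: BaselineProfile
) -> float:
    """Maximum absolute deviation from the baseline profile, in degrees."""
    if not stride.complete:
        raise ValueError(
            f"stride {stride.index} is incomplete; spatial error undefined")
    if baseline.task_side and baseline.task_side != trace.perturbed_side:
        raise ValueError(
            f"baseline was built for a {baseline.task_side}-side task but the "
            f"trace is a {trace.perturbed_side}-side task")
    profile = _resample_stride(stride, trace, len(baseline.grid))
    return float(np.max(np.abs(profile - baseline.mean_angle)))


def motor_error_table(
    strides: Sequence[Stride],
    trace: StepperTrace,
    baseline: BaselineProfile,
    pacing_rate: float = 60.0,
) -> pd.DataFrame:
    """Per-stride error table (complete strides only)."""
    rows = []
    for s in strides:
        if not s.complete:
            continue
        rows.append({
            "stride_idx": s.index,
            "block": s.block,
            "is_catch": s.is_catch,
            "is_perturbed": s.is_perturbed,
            "time_s": s.onset_time,
            "temporal_error_s": temporal_error(s, pacing_rate),
            "spatial_error_deg": spatial_error(s, trace, baseline),
        })
    return pd.DataFrame(rows)
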
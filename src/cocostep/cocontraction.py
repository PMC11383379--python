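"""Agonist/antagonist role assignment and the fixed cocontraction index (CCI).

The recumbent stepper is a one-degree-of-freedom device: the contralateral
arm and leg extend together, so for every muscle pair there is a unique
muscle that could drive the stepper by itself during each half of the
stride.  That muscle is the *agonist* of the pair for that step; the roles
are fixed by the device mechanics and depend on the task side (which leg
receives the perturbations) and the step phase (perturbed step = extension
of the perturbed leg, recovery step = extension of the contralateral leg).

The fixed cocontraction index for a step is

    CCI = 2 * I_antagonist / (I_agonist + I_antagonist)

where ``I`` are integrals of the normalized EMG linear envelopes over the
step.  CCI < 1 means the pair mainly drives the motion, CCI > 1 means it
resists it, and CCI close to 1 means the pair either trades roles within the
step or is not active at all.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Canonical muscle abbreviations (side prefix + muscle).
MUSCLES = ("TA", "SO", "RF", "ST", "AD", "PD")
SIDES = ("L", "R")

#: The 12 canonical channel labels, e.g. ``"LTA"`` = left tibialis anterior.
CHANNEL_LABELS = tuple(f"{s}{m}" for s in SIDES for m in MUSCLES)

#: The six agonist-antagonist muscle pairs.
PAIRS = (
    "LAD-LPD",
    "LRF-LST",
    "LTA-LSO",
    "RAD-RPD",
    "RRF-RST",
    "RTA-RSO",
)

STEP_PHASES = ("perturbed_step", "recovery_step")
TASK_SIDES = ("left", "right")

# Agonist of each pair, keyed by (pair, task_side, step_phase).  One entry
# per pair x side x phase = 24 entries.  The perturbed step of a left-side
# task is a left-leg extension; driving it takes the left soleus, left
# rectus femoris, left posterior deltoid, right tibialis anterior, right
# semitendinosus and right anterior deltoid, and the roles swap for the
# recovery step (with the exception of the posterior deltoids, which drive
# in both directions on their own side's handle).
_AGONIST_TABLE: dict[tuple[str, str, str], str] = {
    # pair                 side     phase              agonist
    ("LAD-LPD", "left", "perturbed_step"): "LPD",
    ("LAD-LPD", "left", "recovery_step"): "LPD",
    ("LAD-LPD", "right", "perturbed_step"): "LPD",
    ("LAD-LPD", "right", "recovery_step"): "LPD",
    ("LRF-LST", "left", "perturbed_step"): "LRF",
    ("LRF-LST", "left", "recovery_step"): "LST",
    ("LRF-LST", "right", "perturbed_step"): "LST",
    ("LRF-LST", "right", "recovery_step"): "LRF",
    ("LTA-LSO", "left", "perturbed_step"): "LSO",
    ("LTA-LSO", "left", "recovery_step"): "LTA",
    ("LTA-LSO", "right", "perturbed_step"): "LTA",
    ("LTA-LSO", "right", "recovery_step"): "LSO",
    ("RAD-RPD", "left", "perturbed_step"): "RAD",
    ("RAD-RPD", "left", "recovery_step"): "RPD",
    ("RAD-RPD", "right", "perturbed_step"): "RPD",
    ("RAD-RPD", "right", "recovery_step"): "RAD",
    ("RRF-RST", "left", "perturbed_step"): "RST",
    ("RRF-RST", "left", "recovery_step"): "RRF",
    ("RRF-RST", "right", "perturbed_step"): "RRF",
    ("RRF-RST", "right", "recovery_step"): "RST",
    ("RTA-RSO", "left", "perturbed_step"): "RTA",
    ("RTA-RSO", "left", "recovery_step"): "RSO",
    ("RTA-RSO", "right", "perturbed_step"): "RSO",
    ("RTA-RSO", "right", "recovery_step"): "RTA",
}


def pair_members(pair: str) -> tuple[str, str]:
    """Return the two channel labels of a muscle pair, e.g. ``("LTA", "LSO")``."""
    if pair not in PAIRS:
        raise KeyError(f"unknown muscle pair {pair!r}; expected one of {PAIRS}")
    a, b = pair.split("-")
    return a, b


def agonist_for(pair: str, task_side: str, step_phase: str) -> str:
    """Agonist muscle of ``pair`` for a given task side and step phase.

    Parameters
    ----------
    pair : str
        One of the six canonical pairs, e.g. ``"LTA-LSO"``.
    task_side : {"left", "right"}
        Side of the leg receiving the perturbations.
    step_phase : {"perturbed_step", "recovery_step"}
        Half of the stride the step belongs to.
    """
    key = (pair, task_side, step_phase)
    if key not in _AGONIST_TABLE:
        raise KeyError(
            f"no agonist assignment for pair={pair!r}, task_side={task_side!r}, "
            f"step_phase={step_phase!r}"
        )
    return _AGONIST_TABLE[key]


def antagonist_for(pair: str, task_side: str, step_phase: str) -> str:
    """Antagonist muscle of ``pair``: the member that is not the agonist."""
    agonist = agonist_for(pair, task_side, step_phase)
    a, b = pair_members(pair)
    return b if agonist == a else a


def agonist_table() -> pd.DataFrame:
    """The full 24-row agonist assignment table as a tidy DataFrame."""
    rows = [
        {"pair": p, "task_side": s, "step_phase": ph, "agonist": m}
        for (p, s, ph), m in _AGONIST_TABLE.items()
    ]
    return pd.DataFrame(rows)


def cci(i_agonist: float, i_antagonist: float, activity_floor: float = 0.0) -> float:
    """Fixed cocontraction index ``2 * I_ant / (I_ag + I_ant)``.

    Returns NaN when the summed activity is below ``activity_floor`` (the
    pair is considered inactive: a silent pair would otherwise produce an
    arbitrary 0/0).  Raises on negative integrals, which cannot arise from
    a rectified envelope.
    """
    if i_agonist < 0 or i_antagonist < 0:
        raise ValueError(
            f"envelope integrals must be nonnegative, got "
            f"({i_agonist}, {i_antagonist})"
        )
    total = i_agonist + i_antagonist
    if total <= activity_floor or total == 0.0:
        return math.nan
    return 2.0 * i_antagonist / total


def step_integrals(
    envelope_time: np.ndarray,
    envelopes: pd.DataFrame,
    window: tuple[float, float],
    pair: str,
    task_side: str,
    step_phase: str,
) -> tuple[float, float]:
    """Trapezoidal envelope integrals of a pair's muscles over a step window.

    ``window`` is the real-time step interval in seconds: ``[onset,
    contra_onset)`` for the perturbed step and ``[contra_onset, end)`` for
    the recovery step.  Integration is in real time, with the window edges
    interpolated between envelope samples.
    """
    agonist = agonist_for(pair, task_side, step_phase)
    antagonist = antagonist_for(pair, task_side, step_phase)
    for ch in (agonist, antagonist):
        if ch not in envelopes.columns:
            raise KeyError(f"channel {ch!r} missing from envelope set")
    t0, t1 = window
    if not t1 > t0:
        raise ValueError(f"empty or inverted step window {window}")
    i_ag = _trapz_window(envelope_time, envelopes[agonist].to_numpy(), t0, t1)
    i_ant = _trapz_window(envelope_time, envelopes[antagonist].to_numpy(), t0, t1)
    return i_ag, i_ant


def _trapz_window(t: np.ndarray, y: np.ndarray, t0: float, t1: float) -> float:
    """Trapezoidal integral of sampled ``y(t)`` over ``[t0, t1]`` with
    interpolated endpoints."""
    if t0 < t[0] or t1 > t[-1]:
        raise ValueError(
            f"step window [{t0:.3f}, {t1:.3f}] s outside envelope span "
            f"[{t[0]:.3f}, {t[-1]:.3f}] s"
        )
    lo, hi = np.searchsorted(t, [t0, t1])
    # interior samples plus interpolated edge values
    tt = np.concatenate(([t0], t[lo:hi], [t1]))
    yy = np.concatenate((
        [np.interp(t0, t, y)],
        y[lo:hi],
        [np.interp(t1, t, y)],
    ))
    return float(np.trapezoid(yy, tt))


def stride_cci_table(
    envelope_time: np.ndarray,
    envelopes: pd.DataFrame,
    strides: Iterable,
    task_side: str,
    activity_floor_frac: float = 0.05,
) -> pd.DataFrame:
    """Per-(stride, step phase, pair) envelope integrals and CCI.

    ``activity_floor_frac`` scales the inactivity threshold: a pair is
    flagged inactive when I_ag + I_ant falls below ``frac * 2 *
    step_duration``, i.e. below ``frac`` of what two grand-mean-level
    (normalized value 1.0) envelopes would integrate to over the step.
    """
    records = []
    for stride in strides:
        if not stride.complete:
            continue
        windows = {
            "perturbed_step": (stride.onset_time, stride.contra_onset_time),
            "recovery_step": (stride.contra_onset_time, stride.end_time),
        }
        for phase, window in windows.items():
            duration = window[1] - window[0]
            floor = activity_floor_frac * 2.0 * duration
            for pair in PAIRS:
                i_ag, i_ant = step_integrals(
                    envelope_time, envelopes, window, pair, task_side, phase
                )
                value = cci(i_ag, i_ant, activity_floor=floor)
                records.append(
                    {
                        "stride_idx": stride.index,
                        "block": stride.block,
                        "is_catch": stride.is_catch,
                        "is_perturbed": stride.is_perturbed,
                        "time_s": stride.onset_time,
                        "step_phase": phase,
                        "pair": pair,
                        "i_agonist": i_ag,
                        "i_antagonist": i_ant,
                        "cci": value,
                        "active": not math.isnan(value),
                    }
                )
    return pd.DataFrame.from_records(records)


def classify_pairs(
    smoothed: pd.DataFrame,
    significance: Mapping[tuple[str, str], np.ndarray] | None = None,
) -> pd.DataFrame:
    """Label each (time bin, pair, step phase) as driving, resisting or neutral.

    ``smoothed`` is a tidy frame with columns ``time_s``, ``pair``,
    ``step_phase`` and ``cci`` (the per-bin point estimate; NaN = inactive).
    A pair drives when CCI < 1 and resists when CCI > 1; inactive or
    exactly-1 bins are neutral.  If ``significance`` maps (pair, step_phase)
    to a boolean per-bin mask (e.g. cluster-test outcomes), non-significant
    bins are demoted to neutral.
    """
    out = smoothed.copy()
    value = out["cci"].to_numpy(dtype=float)
    label = np.where(np.isnan(value), "neutral",
                     np.where(value < 1.0, "driving",
                              np.where(value > 1.0, "resisting", "neutral")))
    if significance is not None:
        for (pair, phase), mask in significance.items():
            sel = (out["pair"] == pair) & (out["step_phase"] == phase)
            idx = np.flatnonzero(sel.to_numpy())
            if len(idx) != len(mask):
                raise ValueError(
                    f"significance mask for ({pair}, {phase}) has length "
                    f"{len(mask)}, expected {len(idx)}"
                )
            demote = idx[~np.asarray(mask, dtype=bool)]
            label[demote] = "neutral"
    out["label"] = label
    return out


def resistance_ratio(classified: pd.DataFrame) -> pd.DataFrame:
    """Fraction of resisting pair-phase entries per time bin.

    Every bin must carry all 12 entries (6 pairs x 2 step phases); the
    ratio is ``n_resisting / 12``.
    """
    n_total = len(PAIRS) * len(STEP_PHASES)
    rows = []
    for time_s, group in classified.groupby("time_s", sort=True):
        if len(group) != n_total:
            raise ValueError(
                f"time bin {time_s} has {len(group)} pair-phase entries, "
                f"expected {n_total}"
            )
        n_resisting = int((group["label"] == "resisting").sum())
        rows.append(
            {
                "time_s": time_s,
                "n_resisting": n_resisting,
                "n_total": n_total,
                "ratio": n_resisting / n_total,
            }
        )
    return pd.DataFrame(rows)
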
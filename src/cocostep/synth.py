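"""Synthetic perturbed recumbent-stepping protocol, kinematics and EMG.

Emulates a 10-minute stepping task: 2 min of unperturbed stepping (pre),
6 min of perturbed strides with one random catch stride in every window of
five, and 2 min of unperturbed stepping (post), paced at 60 steps/min so
that the nominal stride lasts 2 s.  Perturbations are brief (200 ms)
resistance increases triggered at the extension onset or midextension of
the targeted leg; kinematically they appear here as a localized deviation
of the stepper angle of configurable amplitude.

The generator knows its own ground truth (stride event times, perturbation
command times, per-pair cocontraction targets), which makes every
downstream stage testable by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import signal

from .cocontraction import (
    CHANNEL_LABELS,
    PAIRS,
    STEP_PHASES,
    agonist_for,
    pair_members,
)

PERTURBATION_WINDOWS = ("extension_onset", "midextension")
PERTURBED_SIDES = ("left", "right")
BLOCKS = ("pre", "perturbed", "post")

#: Scheduled perturbation latency as a fraction of the stride, per trigger
#: window.  Extension onset is the start of the stride; midextension is the
#: 50%-range crossing of the extension half-cycle, i.e. a quarter stride
#: into a sinusoidal profile.
_WINDOW_FRACTION = {"extension_onset": 0.0, "midextension": 0.25}


class ConfigurationError(ValueError):
    """A protocol or profile field is out of its valid range."""


@dataclass(frozen=True)
class ProtocolConfig:
    """Timing and hardware parameters of one perturbed stepping task."""

    pacing_rate: float = 60.0           # steps per minute
    pre_duration: float = 120.0         # s
    perturbed_duration: float = 360.0   # s
    post_duration: float = 120.0        # s
    perturbation_duration: float = 0.200  # s of added resistance
    perturbation_gain: float = 3.0      # resistance multiplier (metadata)
    perturbation_window: str = "extension_onset"
    perturbed_side: str = "left"
    catch_period: int = 5               # strides per catch stride
    kinematic_rate: float = 100.0       # Hz
    emg_rate: float = 1100.0            # Hz
    perturbation_decay: float = 0.5     # s; kinematic deviation settle time
    angle_range: float = 60.0           # deg, stepper range of motion

    def __post_init__(self) -> None:
        for name in ("pacing_rate", "pre_duration", "perturbed_duration",
                     "post_duration", "perturbation_duration",
                     "kinematic_rate", "emg_rate", "angle_range"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive, got {getattr(self, name)}")
        if self.catch_period < 2:
            raise ConfigurationError(
                f"catch_period must be >= 2, got {self.catch_period}")
        if self.perturbation_duration >= self.stride_duration:
            raise ConfigurationError(
                f"perturbation_duration ({self.perturbation_duration} s) must be "
                f"shorter than one stride ({self.stride_duration} s)")
        if self.perturbation_window not in PERTURBATION_WINDOWS:
            raise ConfigurationError(
                f"perturbation_window must be one of {PERTURBATION_WINDOWS}, "
                f"got {self.perturbation_window!r}")
        if self.perturbed_side not in PERTURBED_SIDES:
            raise ConfigurationError(
                f"perturbed_side must be one of {PERTURBED_SIDES}, "
                f"got {self.perturbed_side!r}")

    @property
    def stride_duration(self) -> float:
        """Nominal stride duration in s (two steps at the pacing rate)."""
        return 2.0 * 60.0 / self.pacing_rate

    @property
    def total_duration(self) -> float:
        return self.pre_duration + self.perturbed_duration + self.post_duration


def n_perturbation_types() -> int:
    """Number of distinct perturbation types (trigger window x side)."""
    return len(PERTURBATION_WINDOWS) * len(PERTURBED_SIDES)


@dataclass(frozen=True)
class SubjectProfile:
    """Ground-truth generating parameters for one synthetic subject.

    ``target_cci`` maps (pair, step_phase) to the cocontraction index the
    generated EMG should reproduce through the full processing chain.
    ``temporal_error_scale`` is the SD of stride-duration jitter,
    ``spatial_error_scale`` the amplitude (deg) of the kinematic deviation
    injected into perturbed strides, and ``envelope_noise_sd`` the relative
    SD of stride-to-stride EMG burst-amplitude jitter.
    """

    group: str = "young"
    target_cci: Mapping[tuple[str, str], float] = field(default_factory=dict)
    temporal_error_scale: float = 0.05   # s
    spatial_error_scale: float = 10.0    # deg
    envelope_noise_sd: float = 0.2       # relative
    seed: int = 0

    def __post_init__(self) -> None:
        for key, value in self.target_cci.items():
            if not (0.0 <= value < 2.0):
                raise ConfigurationError(
                    f"target CCI for {key} must be in [0, 2), got {value}")
        if self.temporal_error_scale < 0 or self.spatial_error_scale < 0:
            raise ConfigurationError("error scales must be nonnegative")
        if self.envelope_noise_sd < 0:
            raise ConfigurationError("envelope_noise_sd must be nonnegative")

    @property
    def n_driving_pairs(self) -> int:
        """Number of pair x phase entries with a driving (< 1) CCI target."""
        return sum(1 for v in self.target_cci.values() if v < 1.0)


def build_target_cci(
    n_driving_pairs: int,
    driving_cci: float = 0.6,
    resisting_cci: float = 1.3,
    n_resisting_pairs: int = 0,
    priority: tuple[str, ...] = ("LTA-LSO", "RTA-RSO", "LRF-LST",
                                 "RRF-RST", "RAD-RPD"),
) -> dict[tuple[str, str], float]:
    """Build a target-CCI map with a given number of driving entries.

    Grand-mean envelope normalization ties the two step phases of a pair
    together (see :func:`solve_pair_amplitudes`): for alternating-agonist
    pairs both phases must lie on the same side of 1, so driving/resisting
    status is assigned per pair and odd counts round down to the nearest
    achievable (even) number; the left deltoid pair, whose agonist is the
    same muscle in both phases, can only straddle 1 and is kept neutral.
    At most 10 of 12 entries can therefore drive (or resist), which is
    also the largest driving pool observed in practice.  ``priority``
    orders which pairs drive first; the default puts the shank pairs
    (tibialis anterior–soleus) first, the pattern older adults rely on.
    Remaining pairs resist (``n_resisting_pairs`` entries, assigned from
    the back of the priority list) or stay neutral at 1.0.
    """
    if not 0 <= n_driving_pairs <= len(PAIRS) * 2:
        raise ConfigurationError(
            f"n_driving_pairs must be in [0, 12], got {n_driving_pairs}")
    n_drive = min(n_driving_pairs // 2, len(priority))
    n_resist = min(n_resisting_pairs // 2, len(priority) - n_drive)
    targets: dict[tuple[str, str], float] = {
        (pair, phase): 1.0 for pair in PAIRS for phase in STEP_PHASES
    }
    for i, pair in enumerate(priority):
        if i < n_drive:
            value = driving_cci
        elif i >= len(priority) - n_resist:
            value = resisting_cci
        else:
            continue
        for phase in STEP_PHASES:
            targets[(pair, phase)] = value
    return targets


def young_profile(seed: int = 0, **overrides) -> SubjectProfile:
    """Young-adult profile: most pairs (10/12) drive the stepper."""
    defaults = dict(
        group="young",
        target_cci=build_target_cci(10, driving_cci=0.6),
        temporal_error_scale=0.05,
        spatial_error_scale=12.0,
        envelope_noise_sd=0.2,
        seed=seed,
    )
    defaults.update(overrides)
    return SubjectProfile(**defaults)


def older_profile(seed: int = 0, **overrides) -> SubjectProfile:
    """Older-adult profile: few driving pairs (4/12, shank-led), more
    resisting cocontraction, smaller motor errors."""
    defaults = dict(
        group="older",
        target_cci=build_target_cci(4, driving_cci=0.7, resisting_cci=1.3,
                                    n_resisting_pairs=4),
        temporal_error_scale=0.04,
        spatial_error_scale=8.0,
        envelope_noise_sd=0.2,
        seed=seed,
    )
    defaults.update(overrides)
    return SubjectProfile(**defaults)


@dataclass
class ProtocolTimeline:
    """Ordered stride schedule for one task.

    ``strides`` columns: ``stride_idx``, ``block``, ``is_catch``,
    ``is_perturbed``, ``perturb_offset_s`` (scheduled latency within the
    stride at nominal pacing; NaN when no perturbation is applied).
    """

    config: ProtocolConfig
    strides: pd.DataFrame

    @property
    def n_strides(self) -> int:
        return len(self.strides)

    def block_counts(self) -> pd.Series:
        return self.strides["block"].value_counts()


def generate_timeline(config: ProtocolConfig, seed: int) -> ProtocolTimeline:
    """Lay out the stride schedule of one task.

    Stride counts per block are ``floor(block duration / nominal stride)``.
    Within the perturbed block, every consecutive window of
    ``catch_period`` strides contains exactly one catch stride at a
    seeded-random position (trailing partial windows carry none), which
    makes the 1-in-5 catch ratio exact.
    """
    rng = np.random.default_rng(seed)
    T = config.stride_duration
    n_pre = int(config.pre_duration // T)
    n_pert = int(config.perturbed_duration // T)
    n_post = int(config.post_duration // T)
    offset = _WINDOW_FRACTION[config.perturbation_window] * T

    rows = []
    idx = 0
    for _ in range(n_pre):
        rows.append((idx, "pre", False, False, np.nan)); idx += 1
    catch_slots = set()
    for w0 in range(0, n_pert - config.catch_period + 1, config.catch_period):
        catch_slots.add(w0 + int(rng.integers(config.catch_period)))
    for k in range(n_pert):
        is_catch = k in catch_slots
        rows.append((idx, "perturbed", is_catch, not is_catch,
                     np.nan if is_catch else offset))
        idx += 1
    for _ in range(n_post):
        rows.append((idx, "post", False, False, np.nan)); idx += 1

    frame = pd.DataFrame(
        rows, columns=["stride_idx", "block", "is_catch", "is_perturbed",
                       "perturb_offset_s"])
    return ProtocolTimeline(config=config, strides=frame)


@dataclass
class StepperTrace:
    """Uniformly sampled stepper angle with task metadata and, for
    generated traces, logged ground truth.

    ``events`` (generator traces only) has one row per scheduled stride:
    ``stride_idx``, ``block``, ``is_catch``, ``is_perturbed``, ``onset_s``,
    ``perturb_s`` (command time; NaN if none), ``contra_onset_s``,
    ``end_s``.  ``block_bounds`` maps block name to (start, end) in trace
    time.
    """

    time: np.ndarray
    angle: np.ndarray
    rate: float
    perturbed_side: str
    perturbation_window: str
    block_bounds: dict[str, tuple[float, float]] | None = None
    events: pd.DataFrame | None = None
    config: ProtocolConfig | None = None

    @property
    def command_times(self) -> np.ndarray:
        """Perturbation command times logged by the (virtual) controller."""
        if self.events is None:
            return np.empty(0)
        return self.events["perturb_s"].dropna().to_numpy()

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])


def _base_angle(s: np.ndarray, side: str, angle_range: float) -> np.ndarray:
    """Stepper angle over normalized stride time ``s`` in [0, 1).

    The angle increases during left-limb extension; a stride starts at the
    perturbed leg's extension onset, so left-side tasks start at the
    minimum of the oscillation and right-side tasks at the maximum.
    """
    half = angle_range / 2.0
    if side == "left":
        return half - half * np.cos(2 * np.pi * s)
    return half + half * np.cos(2 * np.pi * s)


def synthesize_stepper_trace(
    timeline: ProtocolTimeline, profile: SubjectProfile
) -> StepperTrace:
    """Render the timeline as a sampled stepper-angle trace.

    Each stride is one full cycle of the quasi-sinusoidal profile over its
    own (jittered) duration, so the time-normalized shape of unperturbed
    strides is exactly the baseline curve.  Perturbed strides additionally
    carry a smooth sin^2 deviation of amplitude ``spatial_error_scale``
    starting at the scheduled perturbation time and lasting
    ``perturbation_duration + perturbation_decay``.  A quarter-stride
    lead-in and tail are appended so the first and last extension-onset
    turning points are interior and detectable.
    """
    if timeline.n_strides == 0:
        raise ConfigurationError("timeline has no strides")
    cfg = timeline.config
    rng = np.random.default_rng(np.random.SeedSequence([profile.seed, 0x5E]))
    T = cfg.stride_duration
    n = timeline.n_strides

    durations = T + rng.normal(0.0, profile.temporal_error_scale, size=n)
    durations = np.clip(durations, 0.5 * T, 1.5 * T)
    lead_in = 0.25 * T
    onsets = lead_in + np.concatenate(([0.0], np.cumsum(durations[:-1])))
    ends = onsets + durations
    frac = _WINDOW_FRACTION[cfg.perturbation_window]

    sched = timeline.strides
    perturbed = sched["is_perturbed"].to_numpy()
    command_times = np.where(perturbed, onsets + frac * durations, np.nan)

    total = ends[-1] + 0.25 * T
    t = np.arange(0.0, total, 1.0 / cfg.kinematic_rate)

    # map each sample to its stride (phantom strides cover lead-in/tail)
    stride_of = np.searchsorted(onsets, t, side="right") - 1
    s_norm = np.empty_like(t)
    head = stride_of < 0
    s_norm[head] = (t[head] - lead_in) / T + 1.0     # last quarter of a phantom stride
    tail = stride_of >= 0
    k = np.clip(stride_of, 0, n - 1)
    s_norm[tail] = (t[tail] - onsets[k[tail]]) / durations[k[tail]]
    angle = _base_angle(np.mod(s_norm, 1.0), cfg.perturbed_side, cfg.angle_range)

    if profile.spatial_error_scale > 0:
        width = cfg.perturbation_duration + cfg.perturbation_decay
        # deviation points along the perturbed leg's extension direction
        # (the angle rises during left extension), so the stride-boundary
        # turning points stay put
        sign = 1.0 if cfg.perturbed_side == "left" else -1.0
        for j in np.flatnonzero(perturbed):
            t0 = command_times[j]
            w = min(width, ends[j] - t0)  # keep the deviation inside the stride
            if w <= 0:
                continue
            sel = (t >= t0) & (t < t0 + w)
            angle[sel] += sign * profile.spatial_error_scale * np.sin(
                np.pi * (t[sel] - t0) / w) ** 2

    events = pd.DataFrame({
        "stride_idx": sched["stride_idx"].to_numpy(),
        "block": sched["block"].to_numpy(),
        "is_catch": sched["is_catch"].to_numpy(),
        "is_perturbed": perturbed,
        "onset_s": onsets,
        "perturb_s": command_times,
        "contra_onset_s": onsets + 0.5 * durations,
        "end_s": ends,
    })
    block_bounds = {}
    for block in BLOCKS:
        sel = events["block"] == block
        if sel.any():
            block_bounds[block] = (float(events.loc[sel, "onset_s"].min()),
                                   float(events.loc[sel, "end_s"].max()))
    return StepperTrace(
        time=t,
        angle=angle,
        rate=cfg.kinematic_rate,
        perturbed_side=cfg.perturbed_side,
        perturbation_window=cfg.perturbation_window,
        block_bounds=block_bounds,
        events=events,
        config=cfg,
    )


@dataclass
class EMGRecording:
    """12-channel raw EMG: signed amplitudes at ~1.1 kHz, labeled by
    muscle and side."""

    time: np.ndarray
    data: pd.DataFrame  # columns = CHANNEL_LABELS
    rate: float

    def __post_init__(self) -> None:
        got = tuple(self.data.columns)
        if sorted(got) != sorted(CHANNEL_LABELS):
            raise ConfigurationError(
                f"EMG channels must be exactly {CHANNEL_LABELS}, got {got}")


def solve_pair_amplitudes(
    c_perturbed: float, c_recovery: float, agonists: tuple[str, str],
    members: tuple[str, str],
) -> dict[str, tuple[float, float]]:
    """Per-muscle burst amplitudes (perturbed step, recovery step) that
    reproduce the pair's CCI targets *after* grand-mean normalization.

    Because each channel is later divided by its own grand-mean envelope,
    the normalized antagonist/agonist ratio in each phase depends on how
    both muscles distribute activity across the two phases.  Writing
    ``r = c / (2 - c)`` for the raw integral ratio a target demands, the
    per-phase shares of each muscle must solve a 2x2 system that is
    singular when ``c_perturbed + c_recovery = 2`` with unequal targets —
    such pairs are not representable under this normalization and raise.
    """
    r1 = c_perturbed / (2.0 - c_perturbed)
    r2 = c_recovery / (2.0 - c_recovery)
    m_x, m_y = members
    ag1, ag2 = agonists

    if ag1 == ag2:
        # One muscle drives both phases (the left deltoid pair).  Each
        # phase ratio is a_i / b_i in terms of per-phase shares, and the
        # shares of each muscle sum to 1, so 1 = r1*bs1 + r2*bs2 forces
        # the two ratios to straddle (or equal) 1.
        if np.isclose(r1, 1.0) and np.isclose(r2, 1.0):
            a = b = 0.5
        elif np.isclose(r1, r2):
            raise ConfigurationError(
                f"CCI targets ({c_perturbed}, {c_recovery}) are not jointly "
                f"representable for same-agonist pair {members}: the two "
                "phases must straddle 1 under grand-mean normalization")
        else:
            b = (r2 - 1.0) / (r2 - r1)
            a = r1 * b
            if not (0.0 <= b <= 1.0 and 0.0 <= a <= 1.0):
                raise ConfigurationError(
                    f"CCI targets ({c_perturbed}, {c_recovery}) are not "
                    f"jointly representable for same-agonist pair {members}")
        antagonist = m_x if m_y == ag1 else m_y
        return {antagonist: (a, 1.0 - a), ag1: (b, 1.0 - b)}

    # alternating agonists: x drives the perturbed step, y the recovery step
    x = ag1
    y = m_y if m_x == ag1 else m_x
    if np.isclose(r1, 1.0) and np.isclose(r2, 1.0):
        p = q = 0.5
    elif (r1 - 1.0) * (r2 - 1.0) <= 0:
        raise ConfigurationError(
            f"CCI targets ({c_perturbed}, {c_recovery}) for pair {members} are "
            "not representable under grand-mean normalization (the two step "
            "phases of a pair must lie strictly on the same side of 1)")
    else:
        p = (r2 - 1.0) / (r1 * r2 - 1.0)
        q = r1 * p
    return {x: (p, 1.0 - p), y: (q, 1.0 - q)}


def _bandlimited_noise(rng: np.random.Generator, n: int, rate: float,
                       band: tuple[float, float] = (30.0, 200.0)) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to ``band`` Hz."""
    sos = signal.butter(4, band, btype="bandpass", fs=rate, output="sos")
    x = signal.sosfilt(sos, rng.standard_normal(n))
    sd = x.std()
    if sd == 0:
        raise ConfigurationError("degenerate carrier noise")
    return x / sd


def synthesize_emg(
    timeline: ProtocolTimeline,
    trace: StepperTrace,
    profile: SubjectProfile,
) -> EMGRecording:
    """Generate 12-channel EMG whose processed CCIs match the profile targets.

    Each channel is band-limited (30–200 Hz) Gaussian noise modulated by a
    smooth per-step gain: the agonist of a pair bursts with a sin^2 shape
    over its step and the antagonist bursts with the amplitude ratio that
    the pair's CCI target demands, with per-muscle amplitudes pre-balanced
    for grand-mean normalization (:func:`solve_pair_amplitudes`).
    ``envelope_noise_sd`` jitters each muscle's burst amplitude per stride.
    """
    if trace.events is None:
        raise ConfigurationError("trace must carry generator events")
    cfg = timeline.config
    side = cfg.perturbed_side
    rng = np.random.default_rng(np.random.SeedSequence([profile.seed, 0xE9]))

    # resolve per-channel amplitudes per step phase
    amp: dict[str, list[float]] = {ch: [0.0, 0.0] for ch in CHANNEL_LABELS}
    for pair in PAIRS:
        c1 = profile.target_cci.get((pair, "perturbed_step"), 1.0)
        c2 = profile.target_cci.get((pair, "recovery_step"), 1.0)
        members = pair_members(pair)
        agonists = (agonist_for(pair, side, "perturbed_step"),
                    agonist_for(pair, side, "recovery_step"))
        shares = solve_pair_amplitudes(c1, c2, agonists, members)
        for muscle, (a1, a2) in shares.items():
            amp[muscle] = [a1, a2]

    n = len(trace.time)
    t = trace.time
    events = trace.events
    gains = {ch: np.zeros(n) for ch in CHANNEL_LABELS}
    n_strides = len(events)
    jitter = rng.normal(0.0, profile.envelope_noise_sd,
                        size=(n_strides, len(CHANNEL_LABELS), 2))
    jitter = np.clip(jitter, -0.9, None)

    onsets = events["onset_s"].to_numpy()
    contras = events["contra_onset_s"].to_numpy()
    ends = events["end_s"].to_numpy()
    for k in range(n_strides):
        for phase_idx, (t0, t1) in enumerate(((onsets[k], contras[k]),
                                              (contras[k], ends[k]))):
            lo, hi = np.searchsorted(t, [t0, t1])
            if hi <= lo:
                continue
            burst = np.sin(np.pi * (t[lo:hi] - t0) / (t1 - t0)) ** 2
            for c, ch in enumerate(CHANNEL_LABELS):
                a = amp[ch][phase_idx]
                if a <= 0:
                    continue
                gains[ch][lo:hi] += a * (1.0 + jitter[k, c, phase_idx]) * burst

    # resample gain curves onto the EMG clock and modulate carriers
    t_emg = np.arange(0.0, t[-1], 1.0 / cfg.emg_rate)
    data = {}
    for ch in CHANNEL_LABELS:
        carrier = _bandlimited_noise(rng, len(t_emg), cfg.emg_rate)
        gain = np.interp(t_emg, t, gains[ch])
        data[ch] = gain * carrier
    frame = pd.DataFrame(data, columns=list(CHANNEL_LABELS))
    return EMGRecording(time=t_emg, data=frame, rate=cfg.emg_rate)


def simulate_subject(
    config: ProtocolConfig, profile: SubjectProfile
) -> tuple[ProtocolTimeline, StepperTrace, EMGRecording]:
    """Convenience wrapper: timeline, stepper trace and EMG for one subject."""
    timeline = generate_timeline(config, seed=profile.seed)
    trace = synthesize_stepper_trace(timeline, profile)
    emg = synthesize_emg(timeline, trace, profile)
    return timeline, trace, emg
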
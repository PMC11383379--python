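"""End-to-end orchestration: simulate -> segment -> errors -> envelopes ->
CCI -> time-course statistics, with seeded determinism and CSV artifacts.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cocontraction import classify_pairs, resistance_ratio, stride_cci_table
from .emg import EnvelopeSet, LinearEnvelope, normalize_envelopes
from .errors import BaselineProfile, baseline_profile, motor_error_table
from .kinematics import (
    Stride,
    assign_perturbation_events,
    detect_stride_events,
    filter_incomplete_strides,
    insert_virtual_perturbation_events,
    strides_to_frame,
)
from .synth import (
    ConfigurationError,
    EMGRecording,
    ProtocolConfig,
    StepperTrace,
    SubjectProfile,
    older_profile,
    simulate_subject,
    young_profile,
)
from .timecourse import (
    SmoothedSeries,
    cluster_one_sample_test,
    group_compare,
    kernel_smooth,
    minute_grid,
)


@dataclass
class SubjectResult:
    """All per-subject tables produced by the analysis chain."""

    subject: str
    group: str
    strides: list[Stride]
    n_dropped: int
    baseline: BaselineProfile
    errors: pd.DataFrame       # per-stride motor errors
    cci: pd.DataFrame          # per (stride, phase, pair) CCI
    envelope_set: EnvelopeSet


def segment_trace(
    trace: StepperTrace,
    config: ProtocolConfig,
    command_times: Sequence[float] | None = None,
) -> tuple[list[Stride], int]:
    """Detect, flag and clean strides for one task.

    Uses logged perturbation command times when available (device log or
    generator ground truth); perturbed-block strides without a command
    become catch strides, unperturbed strides get virtual perturbation
    events at the task's mean latency, and incomplete strides are dropped.
    """
    strides = detect_stride_events(trace)
    commands = (trace.command_times if command_times is None
                else np.asarray(command_times, dtype=float))
    strides = assign_perturbation_events(strides, commands, config)
    strides = insert_virtual_perturbation_events(strides)
    return filter_incomplete_strides(strides)


def analyze_subject(
    trace: StepperTrace,
    emg: EMGRecording,
    config: ProtocolConfig,
    subject: str = "s0",
    group: str = "",
    activity_floor_frac: float = 0.05,
    baseline_skip: int = 5,
) -> SubjectResult:
    """Run the full single-subject chain on one task's recordings."""
    strides, n_dropped = segment_trace(trace, config)

    chain = LinearEnvelope(in_rate=emg.rate)
    raw_env = chain.transform(emg.data.to_numpy())
    env_time = np.arange(raw_env.shape[0]) / chain.out_rate
    env_frame = pd.DataFrame(raw_env, columns=emg.data.columns)
    (env_set,) = normalize_envelopes([env_frame], [env_time],
                                     rate=chain.out_rate)

    pre = [s for s in strides if s.block == "pre"]
    baseline = baseline_profile(pre, trace, skip_initial=baseline_skip)
    error_table = motor_error_table(strides, trace, baseline,
                                    pacing_rate=config.pacing_rate)

    # guard against strides extending past the envelope span (resampler
    # edge); they are rare and only ever the final stride
    span = env_set.time[-1]
    usable = [s for s in strides if s.end_time <= span]
    cci_table = stride_cci_table(env_set.time, env_set.envelopes, usable,
                                 task_side=config.perturbed_side,
                                 activity_floor_frac=activity_floor_frac)
    return SubjectResult(
        subject=subject, group=group, strides=strides, n_dropped=n_dropped,
        baseline=baseline, errors=error_table, cci=cci_table,
        envelope_set=env_set,
    )


def simulate_and_analyze_cohort(
    config: ProtocolConfig,
    profiles: Mapping[str, SubjectProfile],
) -> list[SubjectResult]:
    """Simulate and analyze one subject per profile (keyed by subject id)."""
    results = []
    for subject, profile in profiles.items():
        _, trace, emg = simulate_subject(config, profile)
        results.append(analyze_subject(trace, emg, config,
                                       subject=subject, group=profile.group))
    return results


def cohort_profiles(
    group: str,
    n_subjects: int,
    master_seed: int,
    **overrides: Any,
) -> dict[str, SubjectProfile]:
    """Build per-subject profiles with seeds spawned from a master seed."""
    maker = {"young": young_profile, "older": older_profile}.get(group)
    if maker is None:
        raise ConfigurationError(f"unknown group {group!r}")
    seeds = np.random.SeedSequence(master_seed).generate_state(n_subjects)
    return {
        f"{group}{i:02d}": maker(seed=int(s) % (2**31), **overrides)
        for i, s in enumerate(seeds)
    }


def smooth_cci_timecourses(
    results: Sequence[SubjectResult],
    config: ProtocolConfig,
    per_minute: int = 1,
    bandwidth: float | None = None,
) -> dict[tuple[str, str], SmoothedSeries]:
    """Per-(pair, step phase) smoothed CCI curves across subjects."""
    if bandwidth is None:
        bandwidth = 60.0 / per_minute
    grid = minute_grid(config.total_duration, per_minute)
    frames = []
    for res in results:
        chunk = res.cci.copy()
        chunk["subject"] = res.subject
        # align task time to protocol time (traces carry a short lead-in)
        t0 = min(s.onset_time for s in res.strides)
        chunk["time_s"] = chunk["time_s"] - t0
        frames.append(chunk)
    pooled = pd.concat(frames, ignore_index=True)
    out = {}
    for (pair, phase), group in pooled.groupby(["pair", "step_phase"]):
        out[(pair, phase)] = kernel_smooth(
            group, grid, bandwidth=bandwidth, value_col="cci")
    return out


def smooth_error_timecourses(
    results: Sequence[SubjectResult],
    config: ProtocolConfig,
    per_minute: int = 1,
    bandwidth: float | None = None,
    which: str = "temporal_error_s",
    stride_filter: str | None = None,
) -> SmoothedSeries:
    """Smoothed motor-error curves (``which`` column) across subjects.

    ``stride_filter`` restricts samples to ``"perturbed"`` or ``"catch"``
    strides; by default all complete strides contribute.
    """
    if bandwidth is None:
        bandwidth = 60.0 / per_minute
    grid = minute_grid(config.total_duration, per_minute)
    frames = []
    for res in results:
        chunk = res.errors.copy()
        if stride_filter == "perturbed":
            chunk = chunk[chunk["is_perturbed"]]
        elif stride_filter == "catch":
            chunk = chunk[chunk["is_catch"]]
        chunk = chunk.copy()
        chunk["subject"] = res.subject
        t0 = min(s.onset_time for s in res.strides)
        chunk["time_s"] = chunk["time_s"] - t0
        frames.append(chunk)
    pooled = pd.concat(frames, ignore_index=True)
    return kernel_smooth(pooled, grid, bandwidth=bandwidth, value_col=which)


def subject_resistance_ratios(
    result: SubjectResult,
    config: ProtocolConfig,
    per_minute: int = 1,
) -> pd.DataFrame:
    """Per-minute resistance ratio for one subject.

    Each (pair, phase) is smoothed onto the minute grid, classified by its
    point estimate (driving < 1 < resisting), and the ratio counts
    resisting entries out of 12 per bin.
    """
    grid = minute_grid(config.total_duration, per_minute)
    bandwidth = 60.0 / per_minute
    t0 = min(s.onset_time for s in result.strides)
    rows = []
    for (pair, phase), group in result.cci.groupby(["pair", "step_phase"]):
        chunk = group.copy()
        chunk["subject"] = result.subject
        chunk["time_s"] = chunk["time_s"] - t0
        series = kernel_smooth(chunk, grid, bandwidth=bandwidth,
                               value_col="cci")
        for g, time_s in enumerate(grid):
            rows.append({"time_s": time_s, "pair": pair, "step_phase": phase,
                         "cci": series.values[0, g]})
    classified = classify_pairs(pd.DataFrame(rows))
    ratios = resistance_ratio(classified)
    ratios.insert(0, "subject", result.subject)
    return ratios


@dataclass
class RunConfig:
    """Schema for an end-to-end run."""

    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    n_young: int = 6
    n_older: int = 4
    per_minute: int = 1
    bandwidth: float | None = None
    n_boot: int = 1000
    alpha: float = 0.05
    seed: int | None = None
    out_dir: str = "cocostep_run"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigurationError(
                "seed is required: every stochastic stage must be seeded")
        if self.n_young < 0 or self.n_older < 0:
            raise ConfigurationError("cohort sizes must be nonnegative")

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "RunConfig":
        data = dict(data)
        protocol = ProtocolConfig(**data.pop("protocol", {}))
        return cls(protocol=protocol, **data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        from dataclasses import asdict
        return asdict(self)


def run_pipeline(config: RunConfig) -> dict:
    """Simulate a two-group cohort, run the full analysis, write artifacts.

    Returns a summary dict (also written as JSON) and leaves tidy CSVs
    under ``config.out_dir``.  Identical configs and seeds yield
    byte-identical tables.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).generate_state(4)

    profiles: dict[str, SubjectProfile] = {}
    profiles.update(cohort_profiles("young", config.n_young, int(seeds[0])))
    profiles.update(cohort_profiles("older", config.n_older, int(seeds[1])))

    results = simulate_and_analyze_cohort(config.protocol, profiles)

    # per-subject artifacts
    for res in results:
        sub_dir = out / res.subject
        sub_dir.mkdir(exist_ok=True)
        strides_to_frame(res.strides).to_csv(sub_dir / "events.csv", index=False)
        res.errors.to_csv(sub_dir / "errors.csv", index=False)
        res.cci.to_csv(sub_dir / "cci.csv", index=False)

    by_group = {g: [r for r in results if r.group == g]
                for g in ("young", "older")}

    # CCI time courses and cluster tests vs 1, per pair x phase x group
    cluster_rows = []
    smoothed_frames = []
    for group_name, group_results in by_group.items():
        if not group_results:
            continue
        smoothed = smooth_cci_timecourses(group_results, config.protocol,
                                          per_minute=config.per_minute,
                                          bandwidth=config.bandwidth)
        for (pair, phase), series in smoothed.items():
            frame = series.to_frame()
            frame.insert(0, "group", group_name)
            frame.insert(1, "pair", pair)
            frame.insert(2, "step_phase", phase)
            smoothed_frames.append(frame)
            if series.n_subjects >= 5:
                result = cluster_one_sample_test(
                    series, null_value=1.0, alpha=config.alpha,
                    n_boot=config.n_boot, seed=int(seeds[2]))
                for _, row in result.clusters.iterrows():
                    cluster_rows.append({
                        "group": group_name, "pair": pair, "step_phase": phase,
                        **row.to_dict()})
    pd.concat(smoothed_frames, ignore_index=True).to_csv(
        out / "smoothed_cci.csv", index=False)
    pd.DataFrame(cluster_rows).to_csv(out / "cci_clusters.csv", index=False)

    # per-subject resistance ratios
    ratio_frames = [subject_resistance_ratios(r, config.protocol,
                                              per_minute=config.per_minute)
                    for r in results]
    ratios = pd.concat(ratio_frames, ignore_index=True)
    ratios.to_csv(out / "resistance_ratio.csv", index=False)

    # group contrasts on perturbed-block summaries
    pre_end = config.protocol.pre_duration
    pert_end = pre_end + config.protocol.perturbed_duration
    summary: dict[str, Any] = {"groups": {g: len(rs) for g, rs in by_group.items()}}
    if all(len(rs) >= 3 for rs in by_group.values()):
        cci_means = {}
        ratio_means = {}
        for group_name, group_results in by_group.items():
            per_subject = []
            for res in group_results:
                t0 = min(s.onset_time for s in res.strides)
                sel = res.cci[(res.cci["time_s"] - t0 >= pre_end)
                              & (res.cci["time_s"] - t0 < pert_end)]
                per_subject.append(float(sel["cci"].mean()))
            cci_means[group_name] = np.array(per_subject)
            sel = ratios[(ratios["subject"].str.startswith(group_name))
                         & (ratios["time_s"] >= pre_end)
                         & (ratios["time_s"] < pert_end)]
            ratio_means[group_name] = (
                sel.groupby("subject")["ratio"].mean().to_numpy())
        try:
            cci_cmp = group_compare(cci_means["older"], cci_means["young"])
            summary["cci_older_vs_young"] = {
                "statistic": cci_cmp.statistic, "p": cci_cmp.pvalue,
                "mean_older": float(cci_means["older"].mean()),
                "mean_young": float(cci_means["young"].mean()),
                "n_removed": cci_cmp.n_removed}
            ratio_cmp = group_compare(ratio_means["older"], ratio_means["young"])
            summary["resistance_ratio_older_vs_young"] = {
                "statistic": ratio_cmp.statistic, "p": ratio_cmp.pvalue,
                "mean_older": float(ratio_means["older"].mean()),
                "mean_young": float(ratio_means["young"].mean()),
                "n_removed": ratio_cmp.n_removed}
        except Exception as exc:  # degenerate small cohorts
            warnings.warn(f"group comparison skipped: {exc}")

    config_dict = config.to_dict()
    manifest = {
        "cocostep_version": __version__,
        "config": config_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(config_dict, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "n_subjects": len(results),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    return summary
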
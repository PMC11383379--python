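"""Plain-text interchange: tidy CSV tables plus a JSON task sidecar.

Every stage consumes and produces inspectable text files so module
outputs compose through the filesystem alone: traces as (time_s,
angle_deg), EMG as one column per labeled channel, stride schedules and
events as tidy tables, and task metadata (side, trigger window, rates,
block bounds, command times) as a small JSON sidecar next to the trace.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synth import EMGRecording, ProtocolConfig, ProtocolTimeline, StepperTrace


def write_timeline(timeline: ProtocolTimeline, path: str | Path) -> None:
    timeline.strides.to_csv(path, index=False)


def read_timeline(path: str | Path, config: ProtocolConfig) -> ProtocolTimeline:
    return ProtocolTimeline(config=config, strides=pd.read_csv(path))


def write_trace(trace: StepperTrace, path: str | Path) -> None:
    """Write the kinematic trace and a ``<stem>.task.json`` sidecar."""
    path = Path(path)
    pd.DataFrame({"time_s": trace.time, "angle_deg": trace.angle}).to_csv(
        path, index=False)
    meta = {
        "rate_hz": trace.rate,
        "perturbed_side": trace.perturbed_side,
        "perturbation_window": trace.perturbation_window,
        "block_bounds": trace.block_bounds,
        "command_times_s": list(map(float, trace.command_times)),
    }
    with open(path.with_suffix(".task.json"), "w") as fh:
        json.dump(meta, fh, indent=2)


def read_trace(path: str | Path,
               config: ProtocolConfig | None = None) -> StepperTrace:
    """Read a trace CSV, picking up its task sidecar when present."""
    path = Path(path)
    frame = pd.read_csv(path)
    sidecar = path.with_suffix(".task.json")
    meta = {}
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = json.load(fh)
    events = None
    commands = meta.get("command_times_s")
    if commands:
        events = pd.DataFrame({"perturb_s": np.asarray(commands, dtype=float)})
    bounds = meta.get("block_bounds")
    if bounds is not None:
        bounds = {k: tuple(v) for k, v in bounds.items()}
    return StepperTrace(
        time=frame["time_s"].to_numpy(),
        angle=frame["angle_deg"].to_numpy(),
        rate=float(meta.get("rate_hz", 100.0)),
        perturbed_side=meta.get("perturbed_side", "left"),
        perturbation_window=meta.get("perturbation_window", "extension_onset"),
        block_bounds=bounds,
        events=events,
        config=config,
    )


def write_emg(emg: EMGRecording, path: str | Path) -> None:
    frame = emg.data.round(6).copy()
    frame.insert(0, "time_s", emg.time)
    frame.to_csv(path, index=False, float_format="%.10g")


def read_emg(path: str | Path) -> EMGRecording:
    frame = pd.read_csv(path)
    time = frame.pop("time_s").to_numpy()
    # overall span, not per-sample diffs: robust to text quantization
    rate = (len(time) - 1) / (time[-1] - time[0])
    return EMGRecording(time=time, data=frame, rate=rate)
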
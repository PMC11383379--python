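"""Shared fixtures: synthetic subjects and cohorts at the protocol's
standard conditions (10-min task, 60 steps/min, 200-ms perturbations)."""

from __future__ import annotations

import numpy as np
import pytest

from cocostep import (
    ProtocolConfig,
    SubjectProfile,
    simulate_subject,
)
from cocostep.pipeline import analyze_subject

#: CCI generating values used for parameter-recovery checks: a strongly
#: driving, a neutral, and a strongly resisting level, assigned per pair.
RECOVERY_TARGETS = {
    **{("LTA-LSO", ph): 0.3 for ph in ("perturbed_step", "recovery_step")},
    **{("RRF-RST", ph): 0.3 for ph in ("perturbed_step", "recovery_step")},
    **{("RTA-RSO", ph): 1.7 for ph in ("perturbed_step", "recovery_step")},
    **{("LRF-LST", ph): 1.7 for ph in ("perturbed_step", "recovery_step")},
    **{("LAD-LPD", ph): 1.0 for ph in ("perturbed_step", "recovery_step")},
    **{("RAD-RPD", ph): 1.0 for ph in ("perturbed_step", "recovery_step")},
}


@pytest.fixture(scope="session")
def protocol() -> ProtocolConfig:
    return ProtocolConfig()


@pytest.fixture(scope="session")
def noiseless_subject(protocol):
    """One subject with all noise and deviation scales at zero: the
    segmentation oracle (ground truth is exact)."""
    profile = SubjectProfile(
        group="young", target_cci=dict(RECOVERY_TARGETS),
        temporal_error_scale=0.0, spatial_error_scale=0.0,
        envelope_noise_sd=0.0, seed=101)
    timeline, trace, emg = simulate_subject(protocol, profile)
    result = analyze_subject(trace, emg, protocol, subject="noiseless")
    return {"profile": profile, "timeline": timeline, "trace": trace,
            "emg": emg, "result": result}


@pytest.fixture(scope="session")
def perturbed_subject(protocol):
    """Noiseless subject with a 15-degree injected kinematic deviation on
    perturbed strides (spatial-error recovery oracle)."""
    profile = SubjectProfile(
        group="young", target_cci=dict(RECOVERY_TARGETS),
        temporal_error_scale=0.0, spatial_error_scale=15.0,
        envelope_noise_sd=0.0, seed=102)
    timeline, trace, emg = simulate_subject(protocol, profile)
    result = analyze_subject(trace, emg, protocol, subject="perturbed")
    return {"profile": profile, "timeline": timeline, "trace": trace,
            "emg": emg, "result": result}


@pytest.fixture(scope="session")
def short_protocol() -> ProtocolConfig:
    """A 2-minute task for fast unit-level end-to-end checks."""
    return ProtocolConfig(pre_duration=30.0, perturbed_duration=60.0,
                          post_duration=30.0)


@pytest.fixture(scope="session")
def noisy_cohort(protocol):
    """Ten subjects at the default noise levels with the recovery targets."""
    results = []
    seeds = np.random.SeedSequence(777).generate_state(10)
    for i, s in enumerate(seeds):
        profile = SubjectProfile(
            group="young", target_cci=dict(RECOVERY_TARGETS),
            temporal_error_scale=0.05, spatial_error_scale=10.0,
            envelope_noise_sd=0.2, seed=int(s) % (2**31))
        _, trace, emg = simulate_subject(protocol, profile)
        results.append(analyze_subject(trace, emg, protocol,
                                       subject=f"s{i:02d}"))
    return results
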
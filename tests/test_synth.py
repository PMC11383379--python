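"""Protocol timeline, stepper-trace and EMG generator properties."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cocostep.synth import (
    CHANNEL_LABELS,
    ConfigurationError,
    EMGRecording,
    ProtocolConfig,
    SubjectProfile,
    build_target_cci,
    generate_timeline,
    n_perturbation_types,
    older_profile,
    solve_pair_amplitudes,
    synthesize_emg,
    synthesize_stepper_trace,
    young_profile,
)


class TestProtocolConfig:
    def test_defaults_give_two_second_stride(self):
        assert ProtocolConfig().stride_duration == pytest.approx(2.0)

    def test_four_perturbation_types(self):
        assert n_perturbation_types() == 4

    @pytest.mark.parametrize("field, value", [
        ("pacing_rate", 0.0), ("pre_duration", -1.0), ("catch_period", 1),
        ("perturbation_duration", 2.5), ("perturbation_window", "toe_off"),
        ("perturbed_side", "both"),
    ])
    def test_invalid_fields_named_in_error(self, field, value):
        with pytest.raises(ConfigurationError, match=field.split("_")[0]):
            ProtocolConfig(**{field: value})


class TestTimeline:
    def test_default_block_counts(self):
        tl = generate_timeline(ProtocolConfig(), seed=1)
        counts = tl.block_counts()
        assert counts["pre"] == 60 and counts["post"] == 60
        assert counts["perturbed"] == 180
        assert int(tl.strides["is_catch"].sum()) == 36

    def test_pre_and_post_have_no_flags(self):
        tl = generate_timeline(ProtocolConfig(), seed=2)
        outside = tl.strides[tl.strides["block"] != "perturbed"]
        assert not outside["is_catch"].any()
        assert not outside["is_perturbed"].any()

    def test_seeded_determinism(self):
        a = generate_timeline(ProtocolConfig(), seed=3).strides
        b = generate_timeline(ProtocolConfig(), seed=3).strides
        pd.testing.assert_frame_equal(a, b)

    @given(seed=st.integers(0, 2**16),
           catch_period=st.integers(2, 8),
           perturbed_minutes=st.integers(1, 8))
    @settings(deadline=None, derandomize=True, max_examples=25)
    def test_exactly_one_catch_per_window(self, seed, catch_period,
                                          perturbed_minutes):
        cfg = ProtocolConfig(catch_period=catch_period,
                             perturbed_duration=60.0 * perturbed_minutes)
        tl = generate_timeline(cfg, seed=seed)
        pert = tl.strides[tl.strides["block"] == "perturbed"]
        flags = pert["is_catch"].to_numpy()
        n_windows = len(flags) // catch_period
        for w in range(n_windows):
            assert flags[w * catch_period:(w + 1) * catch_period].sum() == 1
        # trailing partial window carries no catch
        assert flags[n_windows * catch_period:].sum() == 0
        assert flags.sum() == len(flags) // catch_period

    @given(seed=st.integers(0, 2**16))
    @settings(deadline=None, derandomize=True, max_examples=10)
    def test_block_lengths_conserve_duration(self, seed):
        cfg = ProtocolConfig()
        tl = generate_timeline(cfg, seed=seed)
        scheduled = tl.n_strides * cfg.stride_duration
        assert abs(scheduled - cfg.total_duration) <= cfg.stride_duration


class TestStepperTrace:
    def test_noiseless_durations_exact(self):
        cfg = ProtocolConfig()
        tl = generate_timeline(cfg, seed=1)
        profile = SubjectProfile(temporal_error_scale=0.0,
                                 spatial_error_scale=0.0, seed=1)
        trace = synthesize_stepper_trace(tl, profile)
        durations = np.diff(trace.events["onset_s"].to_numpy())
        assert np.allclose(durations, 2.0)
        assert trace.rate == cfg.kinematic_rate

    def test_same_seed_identical(self):
        cfg = ProtocolConfig()
        tl = generate_timeline(cfg, seed=4)
        profile = young_profile(seed=9)
        a = synthesize_stepper_trace(tl, profile)
        b = synthesize_stepper_trace(tl, profile)
        assert np.array_equal(a.angle, b.angle)

    def test_angle_convention_and_range(self):
        """The angle rises during left extension and spans ~0..60 deg."""
        cfg = ProtocolConfig(perturbed_side="left")
        tl = generate_timeline(cfg, seed=1)
        profile = SubjectProfile(temporal_error_scale=0.0,
                                 spatial_error_scale=0.0, seed=1)
        trace = synthesize_stepper_trace(tl, profile)
        onset = trace.events["onset_s"].iloc[0]
        half = (trace.time >= onset) & (trace.time < onset + 1.0)
        assert np.all(np.diff(trace.angle[half]) >= -1e-9)
        assert trace.angle.min() == pytest.approx(0.0, abs=0.1)
        assert trace.angle.max() == pytest.approx(60.0, abs=0.1)

    def test_unperturbed_strides_carry_no_deviation(self):
        cfg = ProtocolConfig()
        tl = generate_timeline(cfg, seed=5)
        clean = SubjectProfile(temporal_error_scale=0.0,
                               spatial_error_scale=0.0, seed=7)
        bumped = SubjectProfile(temporal_error_scale=0.0,
                                spatial_error_scale=15.0, seed=7)
        a = synthesize_stepper_trace(tl, clean)
        b = synthesize_stepper_trace(tl, bumped)
        diff = np.abs(a.angle - b.angle)
        ev = a.events
        for _, row in ev[~ev["is_perturbed"]].iterrows():
            sel = (a.time >= row["onset_s"]) & (a.time < row["end_s"])
            assert diff[sel].max() == pytest.approx(0.0, abs=1e-12)

    def test_empty_timeline_rejected(self):
        cfg = ProtocolConfig()
        tl = generate_timeline(cfg, seed=1)
        tl.strides = tl.strides.iloc[:0]
        with pytest.raises(ConfigurationError):
            synthesize_stepper_trace(tl, SubjectProfile(seed=1))


class TestEMGSynthesis:
    def test_channel_labels_canonical(self, short_protocol):
        tl = generate_timeline(short_protocol, seed=1)
        profile = young_profile(seed=1)
        trace = synthesize_stepper_trace(tl, profile)
        emg = synthesize_emg(tl, trace, profile)
        assert sorted(emg.data.columns) == sorted(CHANNEL_LABELS)

    def test_bad_labels_rejected(self):
        t = np.arange(0, 1, 1 / 1100)
        data = pd.DataFrame({f"ch{i}": np.zeros_like(t) for i in range(12)})
        with pytest.raises(ConfigurationError, match="channels"):
            EMGRecording(time=t, data=data, rate=1100.0)

    def test_same_seed_identical(self, short_protocol):
        tl = generate_timeline(short_protocol, seed=2)
        profile = young_profile(seed=3)
        trace = synthesize_stepper_trace(tl, profile)
        a = synthesize_emg(tl, trace, profile)
        b = synthesize_emg(tl, trace, profile)
        assert np.array_equal(a.data.to_numpy(), b.data.to_numpy())


class TestAmplitudeSolver:
    def test_equal_targets_alternating(self):
        shares = solve_pair_amplitudes(0.5, 0.5, ("LSO", "LTA"), ("LTA", "LSO"))
        r = 0.5 / 1.5
        p = shares["LSO"][0]
        q = shares["LTA"][0]
        assert q / p == pytest.approx(r)
        assert (1 - p) / (1 - q) == pytest.approx(r)

    def test_complementary_targets_unrepresentable(self):
        # c1 + c2 = 2 with c1 != 1 is the singular case
        with pytest.raises(ConfigurationError, match="not representable"):
            solve_pair_amplitudes(0.3, 1.7, ("LSO", "LTA"), ("LTA", "LSO"))

    def test_mixed_sides_unrepresentable(self):
        with pytest.raises(ConfigurationError, match="same side"):
            solve_pair_amplitudes(0.5, 1.2, ("LSO", "LTA"), ("LTA", "LSO"))

    def test_same_agonist_equal_targets_unrepresentable(self):
        with pytest.raises(ConfigurationError, match="straddle"):
            solve_pair_amplitudes(0.6, 0.6, ("LPD", "LPD"), ("LAD", "LPD"))

    def test_same_agonist_straddling_solved(self):
        shares = solve_pair_amplitudes(0.8, 1.2, ("LPD", "LPD"), ("LAD", "LPD"))
        a1, a2 = shares["LAD"]
        b1, b2 = shares["LPD"]
        assert a1 / b1 == pytest.approx(0.8 / 1.2)
        assert a2 / b2 == pytest.approx(1.2 / 0.8)


class TestProfiles:
    def test_driving_pair_counts(self):
        assert young_profile(seed=0).n_driving_pairs == 10
        assert older_profile(seed=0).n_driving_pairs == 4

    def test_build_target_cci_counts(self):
        targets = build_target_cci(6, driving_cci=0.5, resisting_cci=1.4,
                                   n_resisting_pairs=2)
        assert sum(v < 1 for v in targets.values()) == 6
        assert sum(v > 1 for v in targets.values()) == 2
        assert len(targets) == 12

    def test_invalid_target_rejected(self):
        with pytest.raises(ConfigurationError):
            SubjectProfile(target_cci={("LTA-LSO", "perturbed_step"): 2.5})
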
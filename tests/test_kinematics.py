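"""Stride segmentation, event assignment, virtual events, filtering."""

import numpy as np
import pytest

from cocostep.kinematics import (
    DataIntegrityError,
    SegmentationError,
    Stride,
    assign_perturbation_events,
    detect_stride_events,
    filter_incomplete_strides,
    insert_virtual_perturbation_events,
    strides_to_frame,
)
from cocostep.synth import StepperTrace


def sinusoid_trace(duration=120.0, rate=100.0, period=2.0, side="left",
                   blocks=None):
    t = np.arange(0.0, duration, 1.0 / rate)
    angle = 30.0 - 30.0 * np.cos(2 * np.pi * t / period)
    return StepperTrace(time=t, angle=angle, rate=rate, perturbed_side=side,
                        perturbation_window="extension_onset",
                        block_bounds=blocks)


class TestDetection:
    def test_pure_sinusoid_counts_and_durations(self):
        strides = detect_stride_events(sinusoid_trace(duration=120.0))
        complete = [s for s in strides if s.end_time is not None
                    and s.contra_onset_time is not None]
        assert len(complete) in (58, 59, 60)
        durations = np.array([s.duration for s in complete])
        assert np.all(np.abs(durations - 2.0) <= 0.01)  # within one sample

    def test_contra_onset_at_half_stride(self):
        strides = detect_stride_events(sinusoid_trace())
        for s in strides[1:-1]:
            if s.contra_onset_time is not None:
                assert s.contra_onset_time - s.onset_time == pytest.approx(
                    1.0, abs=0.01)

    def test_constant_trace_rejected(self):
        trace = sinusoid_trace()
        trace.angle = np.full_like(trace.angle, 20.0)
        with pytest.raises(SegmentationError, match="oscillatory"):
            detect_stride_events(trace)

    def test_too_short_trace_rejected(self):
        with pytest.raises(SegmentationError, match="shorter"):
            detect_stride_events(sinusoid_trace(duration=3.0))

    def test_nonuniform_sampling_rejected(self):
        trace = sinusoid_trace()
        trace.time = trace.time ** 1.01
        with pytest.raises(SegmentationError):
            detect_stride_events(trace)

    def test_right_side_onsets_at_maxima(self):
        strides = detect_stride_events(sinusoid_trace(side="right"))
        trace = sinusoid_trace(side="right")
        for s in strides[1:4]:
            onset_angle = np.interp(s.onset_time, trace.time, trace.angle)
            assert onset_angle == pytest.approx(60.0, abs=0.1)

    def test_ground_truth_accuracy(self, noiseless_subject):
        """Detected events fall within 20 ms of generator event times."""
        det = strides_to_frame(
            detect_stride_events(noiseless_subject["trace"]))
        gt = noiseless_subject["trace"].events
        n = min(len(det), len(gt))
        onset_err = det["onset_s"].to_numpy()[:n] - gt["onset_s"].to_numpy()[:n]
        contra_err = (det["contra_onset_s"].to_numpy()[:n]
                      - gt["contra_onset_s"].to_numpy()[:n])
        assert np.nanmax(np.abs(onset_err)) < 0.020
        assert np.nanmax(np.abs(contra_err)) < 0.020

    def test_stride_contiguity(self, noiseless_subject):
        strides = detect_stride_events(noiseless_subject["trace"])
        for a, b in zip(strides[:-1], strides[1:]):
            assert a.end_time == pytest.approx(b.onset_time, abs=1e-9)


class TestAssignment:
    def _strides(self, n=6, block="perturbed"):
        return [Stride(index=k, onset_time=2.0 * k, end_time=2.0 * (k + 1),
                       contra_onset_time=2.0 * k + 1.0, block=block)
                for k in range(n)]

    def test_commands_attach_and_catch_flagged(self):
        strides = self._strides(4)
        commands = [0.5, 2.5, 6.5]  # stride 3 gets none -> catch
        assign_perturbation_events(strides, commands)
        assert strides[0].is_perturbed and strides[0].perturbation_time == 0.5
        assert strides[1].is_perturbed
        assert strides[2].is_catch and not strides[2].is_perturbed
        assert strides[3].is_perturbed

    def test_zero_latency_allowed(self):
        strides = self._strides(2)
        assign_perturbation_events(strides, [0.0, 2.0])
        assert strides[0].perturbation_time == 0.0
        assert strides[0].latency == 0.0

    def test_two_commands_in_one_stride_rejected(self):
        strides = self._strides(2)
        with pytest.raises(DataIntegrityError, match="commands"):
            assign_perturbation_events(strides, [0.2, 1.8])

    def test_pre_block_untouched(self):
        strides = self._strides(3, block="pre")
        assign_perturbation_events(strides, [])
        assert not any(s.is_catch or s.is_perturbed for s in strides)

    def test_midextension_latency_quarter_stride(self, protocol):
        """On the noiseless sinusoid, midextension commands land a quarter
        stride after the onset (the 50%-range crossing of extension)."""
        from cocostep.synth import (ProtocolConfig, SubjectProfile,
                                    generate_timeline,
                                    synthesize_stepper_trace)
        cfg = ProtocolConfig(perturbation_window="midextension")
        tl = generate_timeline(cfg, seed=1)
        profile = SubjectProfile(temporal_error_scale=0.0,
                                 spatial_error_scale=0.0, seed=1)
        trace = synthesize_stepper_trace(tl, profile)
        strides = detect_stride_events(trace)
        assign_perturbation_events(strides, trace.command_times, cfg)
        latencies = [s.latency for s in strides if s.is_perturbed]
        assert np.allclose(latencies, 0.5, atol=0.01)


class TestVirtualEvents:
    def _mixed(self, latencies):
        strides = []
        k = 0
        for lat in latencies:
            s = Stride(index=k, onset_time=2.0 * k, end_time=2.0 * (k + 1),
                       contra_onset_time=2.0 * k + 1.0, block="perturbed",
                       is_perturbed=True)
            s.perturbation_time = s.onset_time + lat
            strides.append(s); k += 1
        for block in ("pre", "post"):
            strides.append(Stride(index=k, onset_time=2.0 * k,
                                  end_time=2.0 * (k + 1),
                                  contra_onset_time=2.0 * k + 1.0,
                                  block=block))
            k += 1
        return strides

    def test_mean_latency_applied(self):
        strides = insert_virtual_perturbation_events(self._mixed([0.4, 0.6]))
        virtual = [s for s in strides if s.virtual_perturbation]
        assert len(virtual) == 2
        for s in virtual:
            assert s.latency == pytest.approx(0.5)

    def test_constant_latency(self):
        strides = insert_virtual_perturbation_events(self._mixed([0.5, 0.5]))
        for s in strides:
            assert s.latency == pytest.approx(0.5)

    def test_latency_mean_preserved(self):
        """Mean latency of virtual events equals mean of real events."""
        strides = insert_virtual_perturbation_events(
            self._mixed([0.30, 0.45, 0.75]))
        real = np.mean([s.latency for s in strides if s.is_perturbed])
        virt = np.mean([s.latency for s in strides if s.virtual_perturbation])
        assert virt == pytest.approx(real)

    def test_no_perturbed_strides_rejected(self):
        strides = [Stride(index=0, onset_time=0.0, end_time=2.0,
                          contra_onset_time=1.0, block="pre")]
        with pytest.raises(DataIntegrityError, match="no perturbed"):
            insert_virtual_perturbation_events(strides)


class TestFiltering:
    def test_trailing_partial_stride_dropped(self):
        complete = Stride(index=0, onset_time=0.0, end_time=2.0,
                          contra_onset_time=1.0, perturbation_time=0.5)
        partial = Stride(index=1, onset_time=2.0)  # recording ended
        kept, dropped = filter_incomplete_strides([complete, partial])
        assert kept == [complete]
        assert dropped == 1

    def test_all_complete_is_noop(self):
        strides = [Stride(index=k, onset_time=2.0 * k, end_time=2.0 * (k + 1),
                          contra_onset_time=2.0 * k + 1.0,
                          perturbation_time=2.0 * k + 0.5)
                   for k in range(3)]
        kept, dropped = filter_incomplete_strides(strides)
        assert kept == strides and dropped == 0

    def test_corrupted_stride_removed(self):
        """A stride with a missing contralateral event is excluded; its
        neighbours survive."""
        strides = [Stride(index=k, onset_time=2.0 * k, end_time=2.0 * (k + 1),
                          contra_onset_time=2.0 * k + 1.0,
                          perturbation_time=2.0 * k + 0.5)
                   for k in range(5)]
        strides[2].contra_onset_time = None
        kept, dropped = filter_incomplete_strides(strides)
        assert dropped == 1
        assert [s.index for s in kept] == [0, 1, 3, 4]
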
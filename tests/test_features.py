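import numpy as np
import pytest

from gaitevents.features import (
    CHANNEL_NAMES,
    LabelSequence,
    assemble_features,
    compute_velocity,
    crop_with_buffer,
    make_labels,
    make_sample_weights,
    normalize,
    normalize_tensor,
    pad_batch,
    resample_trial,
)
from gaitevents.gait_core import EventType, GaitEvent, MARKER_NAMES, Side, Trial


def trial_from_markers(markers, events=(), fs=150.0):
    return Trial("t", "s", "HC", fs, markers, list(events))


class TestVelocity:
    def test_linear_ramp_exact(self):
        T = 100
        pos = np.zeros((T, 3))
        pos[:, 0] = 10.0 * np.arange(T)  # 10 mm/frame
        vel = compute_velocity(pos, fs=150.0)
        np.testing.assert_allclose(vel[:, 0], 1500.0)
        np.testing.assert_allclose(vel[:, 1:], 0.0)

    def test_constant_position_zero(self):
        vel = compute_velocity(np.full((50, 3), 7.0), fs=150.0)
        np.testing.assert_allclose(vel, 0.0)

    def test_sinusoid_matches_analytic_derivative(self):
        fs, amp, freq = 150.0, 20.0, 1.0
        t = np.arange(300) / fs
        pos = np.zeros((300, 3))
        pos[:, 0] = amp * np.sin(2 * np.pi * freq * t)
        analytic = amp * 2 * np.pi * freq * np.cos(2 * np.pi * freq * t)
        vel = compute_velocity(pos, fs)[:, 0]
        assert np.abs(vel - analytic).max() < 0.01 * amp * 2 * np.pi

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            compute_velocity(np.zeros((1, 3)), 150.0)


class TestAssemble:
    def test_36_channels_in_documented_order(self, heel_trial_clean):
        ft = assemble_features(heel_trial_clean)
        assert ft.values.shape == (heel_trial_clean.n_frames, 36)
        assert ft.channel_names[0] == "L_HEEL.pos.AP"
        assert ft.channel_names[3] == "L_HEEL.vel.AP"
        assert ft.channel_names[35] == "R_ANKLE.vel.V"
        assert len(CHANNEL_NAMES) == 36
        assert ft.mask.all()

    def test_missing_marker_named(self, heel_trial_clean):
        trial = heel_trial_clean.copy()
        del trial.markers["L_ANKLE"]
        with pytest.raises(ValueError, match="L_ANKLE"):
            assemble_features(trial)


class TestNormalize:
    def test_minmax_to_unit_range(self):
        out = normalize(np.array([[0.0], [5.0], [10.0]]))
        np.testing.assert_allclose(out[:, 0], [0.1, 0.6, 1.1])

    def test_constant_channel_maps_to_floor(self):
        out = normalize(np.full((3, 1), 7.0))
        np.testing.assert_allclose(out[:, 0], 0.1)

    def test_nonconstant_channels_hit_bounds_exactly(self, rng):
        vals = rng.normal(size=(40, 5))
        out = normalize(vals)
        np.testing.assert_allclose(out.min(axis=0), 0.1, atol=1e-12)
        np.testing.assert_allclose(out.max(axis=0), 1.1, atol=1e-12)

    def test_idempotent_on_normalized_channels(self, rng):
        out = normalize(rng.normal(size=(30, 4)))
        np.testing.assert_allclose(normalize(out), out, atol=1e-12)

    def test_masked_frames_stay_zero(self, rng):
        vals = rng.normal(size=(10, 2))
        mask = np.ones(10, bool)
        mask[7:] = False
        out = normalize(vals, mask)
        np.testing.assert_array_equal(out[7:], 0.0)
        assert out[:7].min() == pytest.approx(0.1)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            normalize(np.array([[1.0], [np.nan]]))


class TestCrop:
    def test_buffer_within_bounds(self, heel_trial_clean, rng):
        # first event well inside the recording: cropped first-event index
        # must equal the drawn buffer, in [25, 125]
        for _ in range(10):
            cropped = crop_with_buffer(heel_trial_clean, rng)
            first = cropped.events[0].frame
            assert 25 <= first <= 125

    def test_clamps_at_recording_start(self, heel_trial_clean, rng):
        # first truth event of the heel persona is ~45 frames in: the start
        # buffer clamps to frame 0 whenever the draw exceeds it
        first_orig = heel_trial_clean.events[0].frame
        seen_clamped = False
        for seed in range(20):
            cropped = crop_with_buffer(heel_trial_clean, np.random.default_rng(seed))
            assert cropped.events[0].frame <= first_orig
            if cropped.events[0].frame == first_orig:
                seen_clamped = True
        assert seen_clamped

    def test_deterministic_given_rng_state(self, heel_trial_clean):
        a = crop_with_buffer(heel_trial_clean, np.random.default_rng(5))
        b = crop_with_buffer(heel_trial_clean, np.random.default_rng(5))
        assert a.n_frames == b.n_frames
        assert a.events == b.events

    def test_requires_truth_events(self, rng):
        markers = {m: np.zeros((50, 3)) for m in MARKER_NAMES}
        with pytest.raises(ValueError, match="TRUTH"):
            crop_with_buffer(trial_from_markers(markers), rng)


class TestLabels:
    def test_left_right_classes(self):
        markers = {m: np.zeros((100, 3)) for m in MARKER_NAMES}
        trial = trial_from_markers(
            markers, [GaitEvent("IC", "L", 10), GaitEvent("IC", "R", 50)]
        )
        lab = make_labels(trial, EventType.IC)
        assert lab.classes[10] == 1
        assert lab.classes[50] == 2
        assert (lab.classes != 0).sum() == 2

    def test_event_types_are_independent(self):
        markers = {m: np.zeros((60, 3)) for m in MARKER_NAMES}
        trial = trial_from_markers(
            markers, [GaitEvent("FO", "L", 5), GaitEvent("IC", "R", 30)]
        )
        ic = make_labels(trial, EventType.IC)
        fo = make_labels(trial, EventType.FO)
        assert ic.classes[5] == 0 and ic.classes[30] == 2
        assert fo.classes[5] == 1 and fo.classes[30] == 0

    def test_no_events_of_type_all_zero(self):
        markers = {m: np.zeros((40, 3)) for m in MARKER_NAMES}
        trial = trial_from_markers(markers, [GaitEvent("FO", "L", 5)])
        assert (make_labels(trial, EventType.IC).classes == 0).all()


class TestSampleWeights:
    def test_ratio_ten_weight_sum(self):
        lab = LabelSequence("IC", np.eye(1, 100, 40, dtype=int)[0], np.ones(100))
        weights = make_sample_weights(lab, ratio=10)
        assert weights.sum() == 99 + 10

    def test_ratio_one_uniform(self):
        lab = LabelSequence("IC", np.zeros(20, int), np.ones(20))
        np.testing.assert_array_equal(make_sample_weights(lab, 1), 1.0)

    def test_ratio_below_one_rejected(self):
        lab = LabelSequence("IC", np.zeros(5, int), np.ones(5))
        with pytest.raises(ValueError):
            make_sample_weights(lab, 0.5)


class TestPadBatch:
    def _tensors(self, lengths, rng):
        tensors, labels = [], []
        for i, T in enumerate(lengths):
            markers = {m: rng.normal(size=(T, 3)) for m in MARKER_NAMES}
            trial = trial_from_markers(markers, [GaitEvent("IC", "L", T // 2)])
            trial.trial_id = f"t{i}"
            tensors.append(normalize_tensor(assemble_features(trial)))
            lab = make_labels(trial, EventType.IC)
            labels.append(
                LabelSequence("IC", lab.classes, make_sample_weights(lab, 10))
            )
        return tensors, labels

    def test_right_padding_to_longest(self, rng):
        tensors, labels = self._tensors([50, 70], rng)
        batch = pad_batch(tensors, labels)
        assert batch.values.shape == (2, 70, 36)
        np.testing.assert_array_equal(batch.values[0, 50:], 0.0)
        assert not batch.mask[0, 50:].any()
        np.testing.assert_array_equal(batch.weights[0, 50:], 0.0)

    def test_mask_sums_equal_lengths(self, rng):
        tensors, labels = self._tensors([30, 45, 60], rng)
        batch = pad_batch(tensors, labels)
        np.testing.assert_array_equal(batch.mask.sum(axis=1), [30, 45, 60])

    def test_single_trial_identity(self, rng):
        tensors, labels = self._tensors([40], rng)
        batch = pad_batch(tensors, labels)
        np.testing.assert_array_equal(batch.values[0], tensors[0].values)

    def test_unpad_recovers_originals(self, rng):
        tensors, labels = self._tensors([20, 35], rng)
        batch = pad_batch(tensors, labels)
        for i, ft in enumerate(tensors):
            np.testing.assert_array_equal(batch.values[i][batch.mask[i]], ft.values)

    def test_channel_mismatch_rejected(self, rng):
        tensors, labels = self._tensors([20, 20], rng)
        tensors[1].channel_names = tuple(reversed(tensors[1].channel_names))
        with pytest.raises(ValueError, match="channel"):
            pad_batch(tensors, labels)


class TestResample:
    def test_downsample_to_100hz(self):
        markers = {m: np.zeros((450, 3)) for m in MARKER_NAMES}
        trial = trial_from_markers(markers, [GaitEvent("IC", "L", 150)], fs=150.0)
        out = resample_trial(trial, 100.0)
        assert out.n_frames == 300
        assert out.fs == 100.0
        assert out.events[0].frame == 100

    def test_identity_at_same_rate(self, heel_trial_clean):
        out = resample_trial(heel_trial_clean, heel_trial_clean.fs)
        assert out.n_frames == heel_trial_clean.n_frames
        assert out.events == heel_trial_clean.events
        np.testing.assert_allclose(
            out.markers["L_HEEL"], heel_trial_clean.markers["L_HEEL"], atol=1e-9
        )

    def test_degenerate_rate_rejected(self, heel_trial_clean):
        with pytest.raises(ValueError):
            resample_trial(heel_trial_clean, 0.1)


def test_pipeline_preserves_event_alignment(heel_trial_clean, rng):
    """After crop -> assemble -> normalize, every IC frame still coincides
    with heel-marker ground contact (the channel's minimum, i.e. 0.1)."""
    cropped = crop_with_buffer(heel_trial_clean, rng)
    ft = normalize_tensor(assemble_features(cropped))
    heel_v = {s: ft.channel_names.index(f"{s}_HEEL.pos.V") for s in "LR"}
    for ev in cropped.events_of(etype=EventType.IC):
        col = heel_v[ev.side.value]
        assert ft.values[ev.frame, col] == pytest.approx(0.1, abs=1e-9)
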
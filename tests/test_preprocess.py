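"""Preprocessing: ADC fitting, b1600 extrapolation, resize/crop, z-scoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dwiprost import preprocess as pp
from dwiprost.preprocess import (ACQUIRED_B_VALUES, DWIStudy, NormalizationStats,
                                 assemble_channels, center_crop,
                                 compute_norm_stats, denormalize,
                                 extrapolate_high_b, fit_adc, normalize,
                                 resize_slice)


def mono_exp(s0, adc, shape=(8, 8)):
    return {b: s0 * np.exp(-adc * b) * np.ones(shape) for b in ACQUIRED_B_VALUES}


class TestFitADC:
    def test_noiseless_monoexponential_recovered_exactly(self):
        adc = fit_adc(mono_exp(1000.0, 0.0015))
        assert np.allclose(adc, 0.0015, atol=1e-15)

    def test_constant_signal_gives_zero_adc(self):
        adc = fit_adc({b: np.full((4, 4), 500.0) for b in ACQUIRED_B_VALUES})
        assert np.all(adc == 0.0)

    def test_negative_slope_floored_at_zero(self):
        # signal increasing with b would imply negative diffusivity
        signals = {b: np.full((3, 3), 100.0 + b) for b in ACQUIRED_B_VALUES}
        assert np.all(fit_adc(signals) == 0.0)

    def test_noisy_recovery_matches_independent_lsq_oracle(self, rng):
        s0_true, adc_true, sigma = 800.0, 0.0009, 0.01
        signals = {
            b: s0_true * np.exp(-adc_true * b)
            * (1 + sigma * rng.standard_normal((16, 16)))
            for b in ACQUIRED_B_VALUES
        }
        adc = fit_adc(signals)
        assert np.abs(adc.mean() - adc_true) / adc_true < 0.05
        # per-pixel closed-form oracle via polyfit on (b, ln S)
        bvals = np.array(sorted(signals), dtype=float)
        for (r, c) in [(0, 0), (5, 9), (15, 15)]:
            y = np.log([max(signals[b][r, c], 1e-6) for b in sorted(signals)])
            slope = np.polyfit(bvals, y, 1)[0]
            assert np.isclose(adc[r, c], max(-slope, 0.0), atol=1e-12)

    def test_fewer_than_two_bvalues_rejected(self):
        with pytest.raises(ValueError):
            fit_adc({0: np.ones((2, 2))})


class TestExtrapolateHighB:
    def test_closed_form_value(self):
        out = extrapolate_high_b(np.full((2, 2), 1000.0), np.full((2, 2), 0.001))
        assert np.allclose(out, 1000.0 * np.exp(-1.6))
        assert np.isclose(out[0, 0], 201.8965, atol=1e-3)

    def test_zero_adc_returns_s0(self):
        s0 = np.arange(9.0).reshape(3, 3)
        assert np.array_equal(extrapolate_high_b(s0, np.zeros((3, 3))), s0)

    def test_matches_elementwise_oracle(self, rng):
        s0 = rng.uniform(10, 2000, (12, 12))
        adc = rng.uniform(0, 3e-3, (12, 12))
        out = extrapolate_high_b(s0, adc, 1600)
        assert np.allclose(out, s0 * np.exp(-1600 * adc), rtol=1e-14)

    def test_negative_b_target_rejected(self):
        with pytest.raises(ValueError):
            extrapolate_high_b(np.ones((2, 2)), np.ones((2, 2)), -5)

    def test_round_trip_with_fit(self):
        signals = mono_exp(750.0, 0.0012)
        adc, s0 = fit_adc(signals, return_s0=True)
        assert np.allclose(extrapolate_high_b(s0, adc, 0), 750.0)
        for b in ACQUIRED_B_VALUES:
            assert np.allclose(extrapolate_high_b(s0, adc, b), signals[b])


class TestResizeCrop:
    def test_identity_resize(self):
        img = np.random.default_rng(0).normal(size=(144, 144))
        assert np.array_equal(resize_slice(img), img)

    def test_constant_field_invariant(self):
        out = resize_slice(np.full((140, 140), 7.0))
        assert out.shape == (144, 144)
        assert np.allclose(out, 7.0)

    def test_downsampling_preserves_mean(self):
        checker = np.indices((288, 288)).sum(axis=0) % 2 * 1.0
        out = resize_slice(checker, 144)
        # block-average oracle: mean of a balanced checkerboard is exactly 1/2
        assert abs(out.mean() - checker.mean()) / checker.mean() < 0.01

    def test_center_crop_index_arithmetic(self):
        img = np.add.outer(np.arange(144) * 1000, np.arange(144)).astype(float)
        out = center_crop(img)
        assert out.shape == (66, 66)
        assert out[0, 0] == 39 * 1000 + 39

    def test_identity_crop_and_floor_tiebreak(self):
        img66 = np.random.default_rng(1).normal(size=(66, 66))
        assert np.array_equal(center_crop(img66), img66)
        img67 = np.zeros((67, 67))
        img67[0, 0] = 5.0
        assert center_crop(img67)[0, 0] == 5.0  # offset floor((67-66)/2)=0

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError):
            center_crop(np.ones((50, 50)))


class TestNormalization:
    def test_degenerate_channel_rejected(self):
        stack = np.stack([np.full((4, 4), 5.0), np.full((4, 4), -5.0)], axis=-1)
        with pytest.raises(ValueError):
            compute_norm_stats([stack])

    def test_hand_computed_population_stats(self):
        s1 = np.zeros((2, 2, 1))
        s2 = np.full((2, 2, 1), 2.0)
        stats = compute_norm_stats([s1, s2])
        assert np.allclose(stats.mu, 1.0)
        assert np.allclose(stats.std, 1.0)  # population convention

    def test_matches_flatten_and_reduce_oracle(self, rng):
        stacks = [rng.normal(size=(5, 5, 3)) for _ in range(4)]
        stats = compute_norm_stats(stacks)
        flat = np.concatenate([s.reshape(-1, 3) for s in stacks])
        assert np.allclose(stats.mu, flat.mean(0), atol=1e-10)
        assert np.allclose(stats.std, flat.std(0), atol=1e-10)

    def test_centering_and_unit_step(self):
        stats = NormalizationStats(mu=np.array([2.0]), std=np.array([3.0]))
        assert np.allclose(normalize(np.full((2, 2, 1), 2.0), stats), 0.0)
        assert np.allclose(normalize(np.full((2, 2, 1), 5.0), stats), 1.0)

    def test_self_normalization_gives_zero_mean_unit_std(self, rng):
        stacks = [rng.normal(loc=3, scale=2, size=(6, 6, 2)) for _ in range(5)]
        stats = compute_norm_stats(stacks)
        normed = np.concatenate([normalize(s, stats).reshape(-1, 2) for s in stacks])
        assert np.all(np.abs(normed.mean(0)) < 1e-6)
        assert np.all(np.abs(normed.std(0) - 1) < 1e-6)

    def test_round_trip(self, rng):
        stats = NormalizationStats(mu=rng.normal(size=3), std=rng.uniform(0.5, 2, 3))
        x = rng.normal(size=(4, 4, 3))
        assert np.allclose(denormalize(normalize(x, stats), stats), x, atol=1e-10)

    def test_channel_mismatch_rejected(self):
        stats = NormalizationStats(mu=np.zeros(2), std=np.ones(2))
        with pytest.raises(ValueError):
            normalize(np.zeros((3, 3, 4)), stats)

    @given(mu=st.floats(-10, 10), std=st.floats(0.1, 10),
           val=st.floats(-100, 100))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_normalize_elementwise_property(self, mu, std, val):
        stats = NormalizationStats(mu=np.array([mu]), std=np.array([std]))
        out = normalize(np.full((1, 1, 1), val), stats)
        assert np.isclose(out[0, 0, 0], (val - mu) / std, rtol=1e-12, atol=1e-12)


def _constant_study(shape=(70, 70), n_slices=3):
    slices = [{b: np.full(shape, 500.0) for b in ACQUIRED_B_VALUES}
              for _ in range(n_slices)]
    return DWIStudy("p1", slices, (0, n_slices - 1), 0, [0] * n_slices)


class TestAssembleChannels:
    def test_constant_signals_zero_adc_b1600_equals_b0(self):
        stack = assemble_channels(_constant_study(), 0)
        assert stack.shape == (66, 66, 6)
        assert np.allclose(stack[:, :, 0], 0.0)          # ADC channel
        assert np.allclose(stack[:, :, 5], stack[:, :, 1])  # b1600 == b0

    def test_channel_order_contract(self):
        values = {0: 10.0, 100: 20.0, 400: 30.0, 1000: 40.0}
        # increasing signal with b -> fitted slope positive, ADC floored to 0
        slices = [{b: np.full((70, 70), v) for b, v in values.items()}]
        study = DWIStudy("p2", slices, (0, 0), 0, [0])
        stack = assemble_channels(study, 0)
        for k, b in enumerate((0, 100, 400, 1000), start=1):
            assert np.allclose(stack[:, :, k], values[b])

    def test_output_shape_for_any_input_size(self):
        for shape in [(66, 66), (100, 80), (140, 140), (200, 200)]:
            stack = assemble_channels(_constant_study(shape=shape), 1)
            assert stack.shape == (66, 66, 6)

    def test_slice_outside_prostate_range_rejected(self):
        study = _constant_study(n_slices=4)
        study = DWIStudy("p3", study.slices, (1, 2), 0, [0, 0, 0, 0])
        with pytest.raises(ValueError):
            assemble_channels(study, 0)

    def test_deterministic(self):
        study = _constant_study()
        a = assemble_channels(study, 0)
        b = assemble_channels(study, 0)
        assert np.array_equal(a, b)


class TestDWIStudyInvariants:
    def test_nonpca_with_tumor_labels_rejected(self):
        slices = [{b: np.ones((70, 70)) for b in ACQUIRED_B_VALUES}]
        with pytest.raises(ValueError):
            DWIStudy("x", slices, (0, 0), 0, [1])

    def test_missing_bvalue_rejected(self):
        slices = [{b: np.ones((70, 70)) for b in (0, 100, 400)}]
        with pytest.raises(ValueError):
            DWIStudy("x", slices, (0, 0), 0, [0])

    def test_bad_prostate_range_rejected(self):
        slices = [{b: np.ones((70, 70)) for b in ACQUIRED_B_VALUES}]
        with pytest.raises(ValueError):
            DWIStudy("x", slices, (0, 3), 0, [0])
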
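"""Breathing signal, subject construction, motion model and cohorts."""

import numpy as np
import pytest

from liver4d.core_io import SLICE_INTERVAL_S
from liver4d.phantom import (
    AnatomyParams,
    acquire_pair,
    breathing_signal,
    deform_volume,
    make_cohort,
    make_sequence,
    make_subject,
    sample_training_pairs,
)


class TestBreathingSignal:
    def test_cycle_count_for_reference_duration(self):
        sig = breathing_signal(85.0, seed=2)
        assert 15 <= len(sig.cycles) <= 26  # ~20 cycles in 85 s

    def test_deterministic_per_seed(self):
        a = breathing_signal(30.0, seed=5)
        b = breathing_signal(30.0, seed=5)
        np.testing.assert_array_equal(a.amplitude, b.amplitude)
        assert a.cycles == b.cycles

    def test_zero_depth_collapses_to_drift(self):
        sig = breathing_signal(30.0, {"depth_range": (0.0, 0.0)}, seed=1)
        np.testing.assert_allclose(sig.amplitude, sig.drift)

    def test_bounded_amplitude(self):
        sig = breathing_signal(120.0, seed=9)
        assert sig.amplitude.min() >= 0.0 and sig.amplitude.max() <= 1.0

    def test_cycle_types_alternate(self):
        sig = breathing_signal(40.0, seed=0)
        types = [c["type"] for c in sig.cycles]
        assert types[:4] == ["abdominal", "thoracic", "abdominal", "thoracic"]

    def test_empty_config_rejected(self):
        with pytest.raises(ValueError):
            breathing_signal(10.0, {}, seed=0)
        with pytest.raises(ValueError):
            breathing_signal(10.0, {"types": ()}, seed=0)


class TestMakeSubject:
    def test_mask_fraction_reasonable(self, subject64):
        frac = subject64.liver_mask.mean()
        assert 0.05 < frac < 0.5

    def test_vessel_count_invariant(self):
        with pytest.raises(ValueError, match="vessel_count"):
            AnatomyParams(vessel_count=0)

    def test_seed_contract(self):
        params = AnatomyParams(liver_extent_mm=(30.0, 26.0, 32.0))
        a = make_subject(params, seed=1, grid=32)
        b = make_subject(params, seed=2, grid=32)
        c = make_subject(params, seed=1, grid=32)
        assert not np.array_equal(a.tissue, b.tissue)
        np.testing.assert_array_equal(a.liver_mask, b.liver_mask)  # same ellipsoid
        np.testing.assert_array_equal(a.tissue, c.tissue)

    def test_extent_exceeding_grid_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            make_subject(AnatomyParams(liver_extent_mm=(200.0, 52.0, 64.0)), grid=32)


class TestDeformVolume:
    def test_zero_amplitude_is_identity(self, subject64):
        warped, field = deform_volume(subject64, 0.0)
        np.testing.assert_array_equal(warped.voxels, subject64.static.voxels)
        assert np.all(field.displacement == 0.0)

    def test_uniform_weight_mode_exact_excursion(self, subject64):
        _, field = deform_volume(subject64, 1.0, uniform_weight=True)
        si = field.displacement[..., 2]
        np.testing.assert_allclose(si, subject64.params.max_si_excursion_mm)

    def test_linearity_in_amplitude(self, subject64):
        _, f_half = deform_volume(subject64, 0.5)
        _, f_full = deform_volume(subject64, 1.0)
        m = subject64.liver_mask
        ratio = (
            np.linalg.norm(f_half.displacement[m], axis=-1).mean()
            / np.linalg.norm(f_full.displacement[m], axis=-1).mean()
        )
        assert abs(ratio - 0.5) < 1e-6

    def test_zero_outside_body(self, subject64):
        _, field = deform_volume(subject64, 1.0)
        outside = ~subject64.body_mask
        assert np.all(field.displacement[outside] == 0.0)

    def test_amplitude_bounds_enforced(self, subject64):
        with pytest.raises(ValueError):
            deform_volume(subject64, 1.2)


class TestAcquisition:
    def test_motionless_noiseless_matches_contrast_transformed_static(self):
        sub = make_subject(
            AnatomyParams(liver_extent_mm=(30.0, 26.0, 32.0), noise_sigma=0.0),
            seed=4, grid=32)
        sig = breathing_signal(20.0, {"depth_range": (0.0, 0.0), "drift": 0.0,
                                      "baseline": 0.0}, seed=0)
        sample = acquire_pair(sub, sig, 1.0, int(sub.data_positions[0]))
        expected = sub.contrast_transform(sample.static_at_nav)
        np.testing.assert_allclose(sample.navigator, expected, atol=1e-12)

    def test_sequence_timing_matches_acquisition_rate(self, subject32):
        sig = breathing_signal(70.0, seed=1)
        seq = make_sequence(subject32, sig, int(subject32.data_positions[0]),
                            n_pairs=175)
        span = seq.timestamps_s[-1] - seq.timestamps_s[0]
        assert abs(span - (350 - 1) * SLICE_INTERVAL_S) < 1e-9
        assert abs((seq.timestamps_s[-1] + SLICE_INTERVAL_S) - 58.1) < 0.2

    def test_navigator_position_constant(self, subject32):
        samples = sample_training_pairs(subject32, 12, seed=3)
        navs = {s.static_at_nav.tobytes() for s in samples}
        assert len(navs) == 1

    def test_position_outside_volume_rejected(self, subject32):
        sig = breathing_signal(10.0, seed=0)
        with pytest.raises(ValueError):
            acquire_pair(subject32, sig, 0.5, subject32.grid[0] + 3)


class TestCohorts:
    def test_no_shift_control_matches_distributions(self):
        s0, t0 = make_cohort(3, 3, shift_config=0.0, seed=8, grid=32)
        src_noise = np.mean([s.params.noise_sigma for s in s0])
        tgt_noise = np.mean([t.params.noise_sigma for t in t0])
        assert abs(src_noise - tgt_noise) / src_noise < 0.5  # same distribution

    def test_default_shift_raises_noise_and_extent(self):
        src, tgt = make_cohort(3, 3, shift_config=1.0, seed=8, grid=32)
        assert np.mean([t.params.noise_sigma for t in tgt]) > np.mean(
            [s.params.noise_sigma for s in src]
        )
        assert np.mean([t.liver_mask.mean() for t in tgt]) > np.mean(
            [s.liver_mask.mean() for s in src]
        )

    def test_shift_monotone_in_config(self):
        noises = []
        for sc in (0.0, 0.5, 1.0):
            _, tgt = make_cohort(2, 3, shift_config=sc, seed=8, grid=32)
            noises.append(np.mean([t.params.noise_sigma for t in tgt]))
        assert noises[0] < noises[1] < noises[2]

    def test_reproducible_per_seed(self):
        a = make_cohort(2, 1, seed=5, grid=32)
        b = make_cohort(2, 1, seed=5, grid=32)
        np.testing.assert_array_equal(a[0][0].tissue, b[0][0].tissue)

    def test_cohort_shape(self):
        src, tgt = make_cohort(4, 2, seed=0, grid=32)
        assert len(src) == 4 and len(tgt) == 2
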
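"""Phantom generator: partitions, determinism, and analytic oracles."""
from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import norm

import bonetomo as bt
from bonetomo.phantom import (
    Cylinder,
    Everywhere,
    Geometry,
    HalfSpace,
    Phase,
    PhantomConfigurationError,
    PhantomSpec,
    RodLattice,
    SyntheticCurveSpec,
    WeightSeriesSpec,
    generate_weight_cohort,
)


def two_phase_spec(**overrides):
    defaults = dict(
        shape=(8, 16, 16),
        phases=(
            Phase("low", Everywhere(), 1000),
            Phase("high", HalfSpace(axis=2, cut=8), 3000),
        ),
        blur_sigma=0.0,
        noise_sigma=0.0,
        seed=0,
    )
    defaults.update(overrides)
    return PhantomSpec(**defaults)


class TestGenerateVolume:
    def test_no_blur_no_noise_gives_exactly_the_phase_greys(self, halfvol):
        assert set(np.unique(halfvol.volume.data)) == {1000, 3000}

    def test_label_map_partitions_the_volume(self, soaked_result):
        counts = np.bincount(soaked_result.label_map.ravel())
        assert counts.sum() == np.prod(soaked_result.volume.shape)
        assert len(counts) == len(soaked_result.phase_table)

    def test_rod_lattice_hits_target_fraction_and_records_it(self):
        spec = bt.plug_phantom(state="soaked", trabecular_fraction=0.30, seed=5)
        res = bt.generate_volume(spec)
        achieved = res.metadata["achieved_fraction_bone"]
        assert achieved == pytest.approx(0.30, abs=0.02)
        # the recorded value is the exact voxel-count fraction in the region
        region = spec.phases[1].primitive.indicator(spec.shape, np.random.default_rng())
        bone_index = next(i for i, p in enumerate(spec.phases) if p.label == "bone")
        frac = (res.label_map[region] == bone_index).mean()
        assert frac == pytest.approx(achieved, abs=1e-6)

    def test_seeded_reproducibility_and_seed_sensitivity(self):
        spec = bt.plug_phantom(state="dry", shape=(24, 48, 48), seed=7)
        a = bt.generate_volume(spec)
        b = bt.generate_volume(spec)
        assert np.array_equal(a.volume.data, b.volume.data)
        assert np.array_equal(a.label_map, b.label_map)
        c = bt.generate_volume(bt.plug_phantom(state="dry", shape=(24, 48, 48), seed=8))
        assert not np.array_equal(a.volume.data, c.volume.data)

    def test_blur_preserves_mean_grey(self):
        spec = two_phase_spec(blur_sigma=10.0, voxel_size=7.15, bit_depth=32)
        res = bt.generate_volume(spec)
        clean = bt.generate_volume(two_phase_spec(bit_depth=32))
        # reflect boundary handling keeps the mean to well within 0.1%
        assert res.volume.data.mean() == pytest.approx(
            clean.volume.data.mean(), rel=1e-3
        )

    def test_noise_is_clipped_to_bit_depth(self):
        spec = two_phase_spec(noise_sigma=5000.0, seed=3)
        res = bt.generate_volume(spec)
        assert res.volume.data.min() >= 0
        assert res.volume.data.max() <= 65535

    def test_negative_blur_rejected(self):
        with pytest.raises(ValueError):
            bt.generate_volume(two_phase_spec(blur_sigma=-1.0))

    def test_overlap_error_mode_detects_conflicts(self):
        spec = PhantomSpec(
            shape=(4, 8, 8),
            phases=(
                Phase("bg", Everywhere(), 100),
                Phase("a", HalfSpace(axis=2, cut=2), 200),
                Phase("b", HalfSpace(axis=2, cut=5), 300),
            ),
            blur_sigma=0.0,
        )
        with pytest.raises(PhantomConfigurationError):
            bt.generate_volume(spec, overlap="error")
        res = bt.generate_volume(spec)  # later-wins is the default
        assert res.volume.data[0, 0, 7] == 300

    def test_uncovered_voxels_rejected(self):
        spec = PhantomSpec(
            shape=(4, 8, 8),
            phases=(Phase("a", HalfSpace(axis=2, cut=4), 200),),
            blur_sigma=0.0,
        )
        with pytest.raises(PhantomConfigurationError):
            bt.generate_volume(spec)

    def test_unreachable_rod_fraction_rejected(self):
        lattice = RodLattice(
            region=Cylinder((8, 8), 6), target_fraction=0.99, spacing=8
        )
        spec = PhantomSpec(
            shape=(16, 16, 16),
            phases=(Phase("bg", Everywhere(), 0), Phase("bone", lattice, 100)),
            blur_sigma=0.0,
        )
        with pytest.raises(PhantomConfigurationError):
            bt.generate_volume(spec)


class TestEdgeProfileGenerator:
    def test_cdf_midpoint_sigma_point_and_limits(self):
        x, y = bt.generate_edge_profile(
            mu=0.0, sigma=2.0, levels=(0.0, 1.0), n_points=9, x_range=(-16, 16)
        )
        assert y[4] == pytest.approx(0.5)          # x = µ
        xs, ys = bt.generate_edge_profile(
            mu=0.0, sigma=2.0, levels=(0.0, 1.0), n_points=33, x_range=(-16, 16)
        )
        i = np.argmin(np.abs(xs - 2.0))            # x = µ + σ
        assert ys[i] == pytest.approx(norm.cdf(1.0), abs=1e-12)
        assert ys[0] == pytest.approx(0.0, abs=1e-12)   # x → −∞ limit
        assert ys[-1] == pytest.approx(1.0, abs=1e-12)

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            bt.generate_edge_profile(mu=0.0, sigma=0.0)

    def test_noise_is_seeded(self):
        a = bt.generate_edge_profile(0, 1, noise_sigma=0.1, seed=5)[1]
        b = bt.generate_edge_profile(0, 1, noise_sigma=0.1, seed=5)[1]
        assert np.array_equal(a, b)


class TestCompressionGenerator:
    def test_max_slope_equals_configured_modulus(self):
        spec = SyntheticCurveSpec(bvtv=0.25, noise_sigma=0.0)
        curve = bt.generate_compression_curve(spec)
        stress = curve.data.force_N.values / curve.geometry.area_mm2
        strain = curve.data.displacement_mm.values / curve.geometry.height_mm
        slopes = np.diff(stress) / np.diff(strain)
        assert slopes.max() == pytest.approx(curve.truth["modulus_MPa"], rel=1e-6)

    def test_zero_post_peak_drop_has_no_interior_peak(self):
        from bonetomo import mechanics

        spec = SyntheticCurveSpec(bvtv=0.25, post_peak_drop=0.0, noise_sigma=0.0)
        curve = bt.generate_compression_curve(spec)
        rec = mechanics.normalize(
            curve.data.force_N.values,
            curve.data.displacement_mm.values,
            curve.geometry,
        )
        assert not mechanics.find_failure(rec).clear_peak

    def test_peak_force_increases_with_bone_fraction(self):
        f15 = bt.generate_compression_curve(SyntheticCurveSpec(bvtv=0.15)).data.force_N.max()
        f35 = bt.generate_compression_curve(SyntheticCurveSpec(bvtv=0.35)).data.force_N.max()
        assert f35 > f15

    def test_bad_geometry_rejected(self):
        with pytest.raises(ValueError):
            Geometry(diameter_mm=0.0)


class TestWeightGenerator:
    def test_initial_weight_exact_and_drying_asymptote(self):
        spec = WeightSeriesSpec(drying_times=(3.0, 300.0), noise_sigma=0.0)
        df = bt.generate_weight_series(spec)
        assert df[df.stage == "initial"].weight_g.iloc[0] == spec.initial_weight
        w_end = df[df.stage == "post-dry"].weight_g.iloc[0]
        assert w_end == pytest.approx(
            spec.initial_weight * (1 - spec.loss_fraction), rel=1e-9
        )

    def test_percent_change_at_3h_matches_closed_form(self):
        # 97% of a 10% loss within 3 h  →  −9.7% at the 3 h weighing
        spec = WeightSeriesSpec(loss_fraction=0.10, drying_rate=-np.log(0.03) / 3.0,
                                noise_sigma=0.0)
        df = bt.generate_weight_series(spec)
        w3 = df[(df.time_h == 3.0) & (df.stage != "initial")].weight_g.iloc[0]
        change = (w3 - spec.initial_weight) / spec.initial_weight * 100
        assert change == pytest.approx(-9.7, abs=1e-9)

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            WeightSeriesSpec(drying_times=(-1.0,))

    def test_cohort_is_seeded_and_varied(self):
        logs_a = generate_weight_cohort(5, seed=11)
        logs_b = generate_weight_cohort(5, seed=11)
        for a, b in zip(logs_a, logs_b):
            assert a.equals(b)
        dry = [df[df.stage == "post-dry"].weight_g.iloc[0] for df in logs_a]
        assert np.std(dry) > 0
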
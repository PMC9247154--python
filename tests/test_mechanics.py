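"""Stress-strain normalization, failure detection, modulus, toughness."""
from __future__ import annotations

import numpy as np
import pytest

import bonetomo as bt
from bonetomo import mechanics
from bonetomo.mechanics import (
    PreloadNotReachedError,
    StressStrainRecord,
    export_analysis_table,
    find_failure,
    modulus,
    normalize,
    summarize,
    toughness,
)
from bonetomo.phantom import Geometry, SyntheticCurveSpec


def record(strain, stress, geometry=None):
    return StressStrainRecord(
        strain=np.asarray(strain, float),
        stress=np.asarray(stress, float),
        geometry=geometry or Geometry(),
    )


class TestNormalize:
    def test_stress_uses_cross_sectional_area(self):
        # Ø6 mm → area 28.274 mm²; 2827.4 N → 100 MPa
        force = np.array([0.0, 15.0, 2827.4])
        disp = np.array([0.0, 0.01, 1.0])
        rec = normalize(force, disp, Geometry(6.0, 10.0))
        assert rec.stress[-1] == pytest.approx(100.0, rel=1e-4)

    def test_strain_is_displacement_over_height(self):
        force = np.linspace(0, 100, 11)
        disp = np.linspace(0, 0.2, 11)
        rec = normalize(force, disp, Geometry(6.0, 10.0))
        # after the 15 N crossing, 0.1 mm of further travel = 1% strain
        d0 = np.interp(15.0, force, disp)
        i = np.argmin(np.abs(disp - (d0 + 0.1)))
        assert rec.strain[i - np.searchsorted(force, 15.0) + 1] == pytest.approx(
            (disp[i] - d0) / 10.0
        )

    def test_preload_crossing_is_interpolated(self):
        force = np.array([0.0, 10.0, 20.0, 30.0])
        disp = np.array([0.0, 0.1, 0.2, 0.3])
        rec = normalize(force, disp, Geometry())
        # 15 N is reached at displacement 0.15 mm, between samples
        assert rec.strain[0] == 0.0
        assert rec.strain[1] == pytest.approx((0.2 - 0.15) / 10.0)

    def test_preload_never_reached_raises(self):
        with pytest.raises(PreloadNotReachedError):
            normalize(np.full(10, 5.0), np.linspace(0, 1, 10), Geometry())


class TestFindFailure:
    def test_monotone_curve_has_no_clear_peak(self):
        strain = np.linspace(0, 0.1, 50)
        res = find_failure(record(strain, 1000 * strain))
        assert not res.clear_peak
        assert np.isnan(res.failure_strain)

    def test_generated_peak_recovered(self):
        strain = np.linspace(0, 0.08, 201)
        stress = np.where(strain <= 0.04, 2000 * strain, 80 - 1000 * (strain - 0.04))
        res = find_failure(record(strain, stress))
        assert res.clear_peak
        assert res.failure_strain == pytest.approx(0.04, abs=1e-3)
        assert res.peak_stress == pytest.approx(80.0, rel=1e-3)

    def test_first_clear_peak_wins_over_global_maximum(self):
        strain = np.linspace(0, 1, 400)
        stress = (
            60 * np.exp(-((strain - 0.3) ** 2) / 0.002)
            + 90 * np.exp(-((strain - 0.7) ** 2) / 0.002)
        )
        res = find_failure(record(strain, stress))
        assert res.clear_peak
        assert res.failure_strain == pytest.approx(0.3, abs=0.01)
        assert res.peak_stress == pytest.approx(60.0, rel=0.01)

    def test_too_short_record_rejected(self):
        with pytest.raises(ValueError):
            find_failure(record([0, 0.1], [0, 1]))


class TestModulus:
    def test_exact_line_recovered_exactly(self):
        strain = np.linspace(0, 0.05, 100)
        mod, window = modulus(record(strain, 1500 * strain))
        assert mod == pytest.approx(1500.0, rel=1e-12)

    def test_toe_region_is_excluded_by_max_slope(self):
        strain = np.linspace(0, 0.04, 400)
        # concave-up toe reaching slope 2000 exactly at the 0.01 junction,
        # then a straight line of slope 2000
        toe = 1000 * strain**2 / 0.01
        line = 2000 * (strain - 0.005)
        stress = np.where(strain < 0.01, toe, line)
        mod, window = modulus(record(strain, stress))
        assert mod == pytest.approx(2000.0, rel=0.05)
        assert window[0] >= 0.008

    def test_generator_modulus_recovered_within_5pct_at_1pct_noise(self):
        spec = SyntheticCurveSpec(bvtv=0.3, noise_sigma=0.01 * 300 * 0.3**2, seed=17)
        curve = bt.generate_compression_curve(spec)
        rec = normalize(curve.data.force_N.values, curve.data.displacement_mm.values,
                        curve.geometry)
        fail = find_failure(rec)
        mod, _ = modulus(rec, failure_strain=fail.failure_strain)
        assert mod == pytest.approx(curve.truth["modulus_MPa"], rel=0.05)

    def test_insufficient_prefailure_data_rejected(self):
        strain = np.linspace(0, 0.002, 10)
        with pytest.raises(ValueError):
            modulus(record(strain, 100 * strain), window_strain_width=0.005)


class TestToughness:
    def test_triangle_area_exact_on_its_own_knots(self):
        rec = record([0.0, 0.05], [0.0, 100.0])
        assert toughness(rec, 0.05) == pytest.approx(2.5, abs=1e-15)

    def test_rectangle_area(self):
        rec = record([0.0, 0.05], [100.0, 100.0])
        assert toughness(rec, 0.05) == pytest.approx(5.0, abs=1e-15)

    def test_trapezoid_converges_with_sample_density(self):
        E, sp = 500.0, 18.75
        errors = []
        for n in (50, 100, 200):
            curve = bt.generate_compression_curve(
                SyntheticCurveSpec(bvtv=0.25, noise_sigma=0.0, n_points=n)
            )
            strain = curve.data.displacement_mm.values / 10.0
            stress = curve.data.force_N.values / curve.geometry.area_mm2
            rec = record(strain, stress)
            t = toughness(rec, curve.truth["failure_strain"])
            errors.append(abs(t - curve.truth["toughness_MJ_m3"]))
        # second-order trapezoid: error shrinks ~4x per doubling
        assert errors[2] < errors[0] / 4
        assert errors[2] < errors[1]

    def test_requires_failure_point(self):
        rec = record([0.0, 0.05], [0.0, 100.0])
        with pytest.raises(ValueError):
            toughness(rec, float("nan"))


class TestExportTable:
    def _summaries(self):
        curves = {
            "A": SyntheticCurveSpec(bvtv=0.2, noise_sigma=0.0, seed=1),
            "B": SyntheticCurveSpec(bvtv=0.3, noise_sigma=0.0, seed=2),
            "C": SyntheticCurveSpec(bvtv=0.25, post_peak_drop=0.0, noise_sigma=0.0),
        }
        out = []
        for sid, spec in curves.items():
            c = bt.generate_compression_curve(spec)
            rec = normalize(c.data.force_N.values, c.data.displacement_mm.values,
                            c.geometry)
            out.append(summarize(rec, specimen=sid))
        return out

    def test_specimen_without_clear_peak_is_excluded_with_reason(self):
        summaries = self._summaries()
        bvtvs = {"A": 0.2, "B": 0.3, "C": 0.25}
        groups = {k: "dry" for k in bvtvs}
        campaigns = {k: "c1" for k in bvtvs}
        table, excluded = export_analysis_table(summaries, bvtvs, groups, campaigns)
        assert len(table) == 2
        assert list(excluded.specimen) == ["C"]
        assert excluded.reason.iloc[0] == "no clear peak"

    def test_log_and_quadratic_columns(self):
        summaries = [s for s in self._summaries() if s.clear_peak]
        bvtvs = {"A": 0.2, "B": 0.3}
        table, _ = export_analysis_table(
            summaries, bvtvs, {k: "g" for k in bvtvs}, {k: "c" for k in bvtvs}
        )
        assert np.allclose(table.log_response, np.log(table.response))
        assert np.allclose(table.bvtv_sq, table.bvtv**2)

    def test_missing_specimen_id_raises(self):
        summaries = [s for s in self._summaries() if s.clear_peak]
        with pytest.raises(KeyError):
            export_analysis_table(summaries, {"A": 0.2}, {"A": "g"}, {"A": "c"})


class TestEndToEndRecovery:
    def test_rank_correlation_with_generator_truth(self):
        """Seeded batch over BV/TV 0.1–0.4 at 2% stress noise: recovered
        modulus, peak stress and toughness preserve the generator ordering."""
        from scipy.stats import spearmanr

        rng = np.random.default_rng(99)
        bvtvs = np.linspace(0.1, 0.4, 30)
        truth = {"modulus_MPa": [], "peak_stress_MPa": [], "toughness_MJ_m3": []}
        rec_vals = {"modulus": [], "peak_stress": [], "toughness": []}
        for i, f in enumerate(bvtvs):
            sp = 300 * f**2
            spec = SyntheticCurveSpec(bvtv=float(f), noise_sigma=0.02 * sp,
                                      seed=int(rng.integers(2**31)))
            c = bt.generate_compression_curve(spec)
            rec = normalize(c.data.force_N.values, c.data.displacement_mm.values,
                            c.geometry)
            s = summarize(rec, specimen=str(i))
            assert s.clear_peak
            for k in truth:
                truth[k].append(c.truth[k])
            rec_vals["modulus"].append(s.modulus)
            rec_vals["peak_stress"].append(s.peak_stress)
            rec_vals["toughness"].append(s.toughness)
        for tk, rk in (("modulus_MPa", "modulus"),
                       ("peak_stress_MPa", "peak_stress"),
                       ("toughness_MJ_m3", "toughness")):
            rho = spearmanr(truth[tk], rec_vals[rk]).statistic
            assert rho >= 0.95
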
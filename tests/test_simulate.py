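"""Ground-truth generators: determinism, physical limits, round trips."""

import numpy as np
import pytest

from cellmech import (PLRParams, fit_ting, hertz_force, kinetics_auc,
                      load_presets, phagocytic_metrics)
from cellmech.errors import DomainError, GenerationError
from cellmech.simulate import (CohortPreset, CurveSpec, simulate_cell_map,
                               simulate_cohort, simulate_curve,
                               simulate_cytometry_sample,
                               simulate_kinetics_trace)


class TestCurveGenerator:
    def test_same_seed_bit_identical(self):
        spec = CurveSpec(params=PLRParams(E1=3000.0, alpha=0.1),
                         noise_rms_nN=0.02, seed=99)
        c1, _ = simulate_curve(spec)
        c2, _ = simulate_curve(spec)
        assert np.array_equal(c1.force_nN, c2.force_nN)
        assert np.array_equal(c1.z_nm, c2.z_nm)

    def test_elastic_approach_matches_hertz_closed_form(self, elastic_curve):
        curve, truth = elastic_curve
        k = curve.spring_constant_N_per_m
        zc = truth["contact_z_nm"]
        sel = slice(truth["contact_index"], curve.turn_index + 1)
        delta = (curve.z_nm[sel] - zc) - curve.force_nN[sel] / k
        ref = hertz_force(np.clip(delta, 0, None), truth["params"].E1,
                          curve.probe)
        assert np.allclose(curve.force_nN[sel], ref, atol=5e-4)

    def test_baseline_and_offset_applied(self):
        spec = CurveSpec(params=PLRParams(E1=2000.0), baseline_offset_nN=0.3,
                         baseline_slope_nN_per_nm=1e-4, seed=1)
        c, _ = simulate_curve(spec)
        pre = c.force_nN[:50]
        assert pre.mean() == pytest.approx(
            0.3 + 1e-4 * c.z_nm[:50].mean(), rel=1e-6)

    def test_round_trip_ting_recovery(self, visco_curve):
        curve, truth = visco_curve
        res = fit_ting(curve)
        assert res.params.E1 == pytest.approx(truth["params"].E1, rel=0.01)
        assert res.params.alpha == pytest.approx(truth["params"].alpha,
                                                 abs=0.01)

    def test_no_contact_spec_rejected(self):
        with pytest.raises(GenerationError):
            CurveSpec(params=PLRParams(E1=1000.0), approach_clearance_nm=4000.0)

    def test_trigger_force_caps_the_ramp(self, visco_curve):
        curve, _ = visco_curve
        approach_peak = curve.force_nN[curve.turn_index]
        assert approach_peak == pytest.approx(1.0, abs=0.1)


class TestMapGenerator:
    def test_substrate_only_map_is_rigid(self):
        fv, truth = simulate_cell_map(apex_height_um=0.0, base_radius_um=5.0,
                                      params=PLRParams(E1=1000.0), grid_n=8,
                                      field_um=20.0, noise_rms_nN=0.0, seed=2)
        assert truth["height_map_um"].max() == 0.0
        c = fv.curves[3, 3]
        k = c.spring_constant_N_per_m
        zc = truth["contact_z_nm"][3, 3]
        sel = c.z_nm > zc
        delta = (c.z_nm[sel] - zc) - c.force_nN[sel] / k
        assert np.max(np.abs(delta)) < 1e-6

    def test_grid_too_small_rejected(self):
        with pytest.raises(DomainError):
            simulate_cell_map(1.0, 5.0, PLRParams(E1=1000.0), grid_n=6,
                              field_um=20.0)

    def test_cap_must_fit_field(self):
        with pytest.raises(GenerationError):
            simulate_cell_map(1.0, 20.0, PLRParams(E1=1000.0), grid_n=8,
                              field_um=20.0)


class TestCohortGenerator:
    def test_presets_load_with_printed_m1_values(self):
        presets = load_presets()
        assert presets["M1_control"].e1_mean_kpa == 2.8
        assert presets["M1_control"].e1_sd_kpa == 1.09
        assert presets["M1_PMA"].e1_mean_kpa == 6.92
        assert presets["M1_PMA"].e1_sd_kpa == 2.87
        # printed height folds encoded in the preset geometry
        assert 4.0 / presets["M1_PMA"].height_mean_um == pytest.approx(1.53, abs=0.01)
        assert 4.0 / presets["M2_PMA"].height_mean_um == pytest.approx(1.69, abs=0.01)

    def test_draws_are_admissible_and_deterministic(self):
        preset = load_presets()["M1_control"]
        rng = np.random.default_rng(5)
        params, apex = preset.draw_cell(rng)
        assert params.E1 > 0 and 0 <= params.alpha <= 1 and apex > 0
        params2, apex2 = preset.draw_cell(np.random.default_rng(5))
        assert (params2, apex2) == (params, apex)

    def test_cohort_structure_and_min_cells(self):
        ctl = CohortPreset(label="c", e1_mean_kpa=3.0, e1_sd_kpa=1.0,
                           alpha_mean=0.2, n_cells=2, grid_n=8, field_um=20.0,
                           base_radius_um=6.0, height_mean_um=2.0)
        act = CohortPreset(label="a", e1_mean_kpa=6.0, e1_sd_kpa=2.0,
                           alpha_mean=0.15, n_cells=2, grid_n=8, field_um=20.0,
                           base_radius_um=6.0, height_mean_um=1.3)
        recs = simulate_cohort(ctl, act, seed=1)
        assert [r["group"] for r in recs] == ["c", "c", "a", "a"]
        assert all("height_map_um" in r["truth"] for r in recs)
        with pytest.raises(GenerationError):
            simulate_cohort(ctl, act, seed=1, n_cells=1)


class TestKineticsGenerator:
    def test_zero_amplitude_zero_auc(self):
        _, truth = simulate_kinetics_trace(peak_amplitude=0.0, seed=1)
        assert truth["auc"] == 0.0

    def test_auc_linear_in_amplitude(self):
        _, t1 = simulate_kinetics_trace(peak_amplitude=500.0, seed=1)
        _, t2 = simulate_kinetics_trace(peak_amplitude=1000.0, seed=1)
        assert t2["auc"] == pytest.approx(2.0 * t1["auc"], rel=1e-12)

    def test_noiseless_auc_matches_analytic(self):
        trace, truth = simulate_kinetics_trace(noise_rms=0.0, dt_s=1.0, seed=1)
        auc = kinetics_auc(trace, trace.t_s[-1])
        assert auc == pytest.approx(truth["auc"], rel=5e-3)

    def test_negative_amplitude_rejected(self):
        with pytest.raises(GenerationError):
            simulate_kinetics_trace(peak_amplitude=-1.0)


class TestCytometryGenerator:
    def test_zero_fraction_zero_affinity(self):
        sample, _ = simulate_cytometry_sample(positive_fraction=0.0,
                                              n_events=2000, seed=3)
        control, _ = simulate_cytometry_sample(positive_fraction=0.0,
                                               n_events=2000, seed=4)
        out = phagocytic_metrics(sample, control)
        assert out["affinity_pct"] < 1.0

    def test_same_seed_identical(self):
        s1, _ = simulate_cytometry_sample(seed=8)
        s2, _ = simulate_cytometry_sample(seed=8)
        assert np.array_equal(s1.intensity, s2.intensity)

    def test_half_fraction_recovered_within_binomial_error(self):
        n = 10_000
        sample, truth = simulate_cytometry_sample(positive_fraction=0.5,
                                                  n_events=n, seed=9)
        control, _ = simulate_cytometry_sample(positive_fraction=0.0,
                                               n_events=5000, seed=10)
        out = phagocytic_metrics(sample, control)
        se = 100.0 * np.sqrt(0.25 / n)
        assert abs(out["affinity_pct"] - 100.0 * truth["n_positive"] / n) < 4 * se + 0.5

    def test_overlapping_modes_flagged(self):
        _, truth = simulate_cytometry_sample(negative_mfi=100.0,
                                             positive_mfi=110.0, seed=1)
        assert truth["overlap_warning"]
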
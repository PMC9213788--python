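"""Properties of the synthetic cardiac cohort generator: surface geometry,
phase coupling, ECG morphology, determinism, and population statistics."""

import dataclasses

import numpy as np
import pytest

from cardiovae.metrics import cavity_volume, clinical_summary
from cardiovae.structures import Phase, PointClass
from cardiovae.synthetic import (
    GeneratorConfig, SubjectFactors, generate_anatomy, generate_ecg,
    generate_population, mean_nn_spacing, sample_factors,
)


class TestFactors:
    def test_deterministic_given_seed(self):
        cfg = GeneratorConfig(seed=5)
        a = sample_factors(5, cfg)
        b = sample_factors(5, cfg)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa.as_vector(), fb.as_vector())

    def test_null_disease_shift_gives_identical_distribution(self):
        cfg = GeneratorConfig(seed=2, disease_shift={})
        healthy = sample_factors(2000, cfg, diseased=False)
        diseased = sample_factors(2000, cfg, diseased=True)
        h = np.vstack([f.as_vector() for f in healthy])
        d = np.vstack([f.as_vector() for f in diseased])
        np.testing.assert_array_equal(h, d)  # same seeds, same means -> same draws

    def test_size_mean_within_clt_bound(self):
        cfg = GeneratorConfig(seed=3)
        sizes = [f.size for f in sample_factors(10_000, cfg)]
        # 3 sd / sqrt(n) bound around the configured mean of 1.0
        assert abs(np.mean(sizes) - 1.0) < 3 * 0.08 / np.sqrt(10_000) + 1e-9

    def test_invalid_contraction_rejected(self):
        with pytest.raises(ValueError, match="contraction"):
            SubjectFactors(contraction=1.2)


class TestAnatomy:
    def test_endo_points_satisfy_ellipsoid_equation(self):
        cfg = GeneratorConfig(n_points_per_class=200, surface_jitter=0.0)
        f = SubjectFactors(tilt=0.0)
        pc = generate_anatomy(f, Phase.ED, 200, 0, cfg)
        a = cfg.lv_short_axis * f.size
        b = a * cfg.lv_axis_ratio * f.elongation
        p = pc.points_by_class[PointClass.LV_ENDO]
        resid = p[:, 0] ** 2 / a ** 2 + p[:, 1] ** 2 / a ** 2 + p[:, 2] ** 2 / b ** 2 - 1
        assert np.abs(resid).max() < 1e-9

    def test_es_cavity_volume_scales_with_contraction_cubed(self):
        cfg = GeneratorConfig(n_points_per_class=2000, surface_jitter=0.0)
        f = SubjectFactors(contraction=0.75)
        ed = generate_anatomy(f, Phase.ED, 2000, 0, cfg)
        es = generate_anatomy(f, Phase.ES, 2000, 0, cfg)
        v_ed = cavity_volume(ed.points_by_class[PointClass.LV_ENDO])
        v_es = cavity_volume(es.points_by_class[PointClass.LV_ENDO])
        assert v_es / v_ed == pytest.approx(0.75 ** 3, rel=0.02)

    def test_tilt_is_a_rotation_of_the_untilted_cloud(self):
        cfg = GeneratorConfig(n_points_per_class=100, surface_jitter=0.3)
        base = dataclasses.replace(SubjectFactors(), tilt=0.0)
        tilted = dataclasses.replace(SubjectFactors(), tilt=15.0)
        pc0 = generate_anatomy(base, Phase.ED, 100, 7, cfg)
        pc15 = generate_anatomy(tilted, Phase.ED, 100, 7, cfg)
        th = np.deg2rad(15.0)
        rot = np.array([[np.cos(th), 0, np.sin(th)], [0, 1, 0],
                        [-np.sin(th), 0, np.cos(th)]])
        for cls in PointClass:
            back = pc15.points_by_class[cls] @ rot  # rotate by -15 degrees
            rms = np.sqrt(((back - pc0.points_by_class[cls]) ** 2).mean())
            assert rms < cfg.surface_jitter

    def test_epicardium_stays_outside_endocardium(self):
        cfg = GeneratorConfig(n_points_per_class=400, surface_jitter=0.0)
        f = SubjectFactors()
        pc = generate_anatomy(f, Phase.ED, 400, 0, cfg)
        a = cfg.lv_short_axis * f.size
        b = a * cfg.lv_axis_ratio * f.elongation
        epi = pc.points_by_class[PointClass.LV_EPI]
        resid = (epi[:, 0] ** 2 / a ** 2 + epi[:, 1] ** 2 / a ** 2
                 + epi[:, 2] ** 2 / b ** 2)
        assert resid.min() > 1.0  # every epi point outside the endo surface


class TestECG:
    def test_deterministic_given_seed(self):
        f = SubjectFactors()
        a = generate_ecg(f, 200, 4)
        b = generate_ecg(f, 200, 4)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_global_gain_removed_by_standardization(self):
        cfg = GeneratorConfig(ecg_noise=0.0)
        f1 = SubjectFactors()
        f2 = dataclasses.replace(f1, r_amp=2 * f1.r_amp, p_amp=2 * f1.p_amp,
                                 t_amp=2 * f1.t_amp)
        a = generate_ecg(f1, 200, 0, cfg)
        b = generate_ecg(f2, 200, 0, cfg)
        np.testing.assert_allclose(a.samples, b.samples, atol=1e-9)

    def test_r_to_t_peak_ratio_increases_with_r_amp(self):
        cfg = GeneratorConfig(ecg_noise=0.0)
        ratios = []
        for r_amp in (0.6, 0.8, 1.0, 1.3, 1.6):
            f = dataclasses.replace(SubjectFactors(), r_amp=r_amp)
            x = generate_ecg(f, 400, 0, cfg).samples
            t = (np.arange(400) + 0.5) / 400
            r_peak = x[np.abs(t - cfg.wave_positions["R"]).argmin()]
            t_peak = x[np.abs(t - cfg.wave_positions["T"]).argmin()]
            ratios.append(r_peak / t_peak)
        assert np.all(np.diff(ratios) > 0)

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError, match=">= 50"):
            generate_ecg(SubjectFactors(), 30, 0)


class TestPopulation:
    def test_counts_and_labels(self, tiny_config):
        pop = generate_population(4, 3, tiny_config)
        assert len(pop) == 7
        assert sum(r.disease for r in pop) == 3
        assert all(r.truth_factors is not None for r in pop)

    def test_pure_function_of_config(self, tiny_config):
        a = generate_population(3, 1, tiny_config)
        b = generate_population(3, 1, tiny_config)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.ecg.samples, rb.ecg.samples)
            for cls in PointClass:
                np.testing.assert_array_equal(ra.ed.points_by_class[cls],
                                              rb.ed.points_by_class[cls])

    def test_all_diseased_population(self, tiny_config):
        pop = generate_population(0, 5, tiny_config)
        assert all(r.disease for r in pop)


@pytest.fixture(scope="module")
def healthy_cohort():
    cfg = GeneratorConfig(n_points_per_class=160, ecg_length=100, seed=21)
    return generate_population(200, 0, cfg)


class TestPopulationStatistics:
    """Slower statistical checks on a moderately sized healthy cohort."""

    def test_mean_lv_ef_in_physiological_band(self, healthy_cohort):
        summary = clinical_summary(healthy_cohort)
        assert 50.0 <= summary["lv_ef"][0] <= 65.0

    def test_size_factor_drives_cavity_volume(self, healthy_cohort):
        size = np.array([r.truth_factors.size for r in healthy_cohort])
        edv = np.array([cavity_volume(r.ed.points_by_class[PointClass.LV_ENDO])
                        for r in healthy_cohort])
        assert np.corrcoef(size, edv)[0, 1] > 0.9

    def test_size_factor_couples_to_r_amplitude(self, healthy_cohort):
        size = np.array([r.truth_factors.size for r in healthy_cohort])
        r_amp = np.array([r.truth_factors.r_amp for r in healthy_cohort])
        assert np.corrcoef(size, r_amp)[0, 1] > 0.5

    def test_truth_factors_separate_disease(self):
        from sklearn.linear_model import LogisticRegression
        from sklearn.model_selection import cross_val_score
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler

        cfg = GeneratorConfig(n_points_per_class=16, ecg_length=100, seed=31)
        pop = generate_population(150, 150, cfg)
        x = np.vstack([r.truth_factors.as_vector() for r in pop])
        y = np.array([r.disease for r in pop])
        auc = cross_val_score(
            make_pipeline(StandardScaler(), LogisticRegression(max_iter=1000)),
            x, y, cv=5, scoring="roc_auc").mean()
        assert auc > 0.95

    def test_nn_spacing_reflects_lattice_sampling(self, healthy_cohort):
        spacing = mean_nn_spacing([healthy_cohort[0].ed])
        # quasi-uniform sampling: spacing near sqrt(area/n), far above the
        # 0.5*sqrt(area/n) of Poisson scatter; just assert a sane mm range
        assert 4.0 < spacing < 15.0
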
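"""Evaluation metrics against brute-force oracles, closed forms, and
hand-computed examples."""

import numpy as np
import pytest

from cardiovae.metrics import (
    CombinedRepresentationBuilder, cavity_volume, chamfer_distance,
    clinical_metrics_for_record, clinical_summary, ejection_fraction, lv_mass,
    mmd, prd, rmse, stroke_volume,
)
from cardiovae.structures import ECGTrace
from cardiovae.synthetic import GeneratorConfig, SubjectFactors, generate_anatomy
from cardiovae.structures import Phase, PointClass


def brute_chamfer(p1, p2, squared):
    d = np.sqrt(((p1[:, None, :] - p2[None, :, :]) ** 2).sum(axis=2))
    if squared:
        d = d ** 2
    return 0.5 * (d.min(axis=1).mean() + d.min(axis=0).mean())


def brute_mmd(x, y, h):
    def k(a, b):
        return np.exp(-((a - b) ** 2).sum() / (2 * h * h))

    n, m = len(x), len(y)
    sxx = sum(k(x[i], x[j]) for i in range(n) for j in range(n) if j != i)
    syy = sum(k(y[i], y[j]) for i in range(m) for j in range(m) if j != i)
    sxy = sum(k(x[i], y[j]) for i in range(n) for j in range(m))
    val = sxx / (n * (n - 1)) + syy / (m * (m - 1)) - 2 * sxy / (n * m)
    return np.sqrt(max(val, 0.0))


class TestChamfer:
    def test_self_distance_is_zero(self, rng):
        p = rng.normal(size=(30, 3))
        assert chamfer_distance(p, p) == 0.0

    @pytest.mark.parametrize("squared,expected", [(False, 5.0), (True, 25.0)])
    def test_singleton_hand_computation(self, squared, expected):
        assert chamfer_distance([[0, 0, 0]], [[3, 4, 0]], squared) == expected

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p1 = rng.normal(size=(rng.integers(5, 200), 3))
        p2 = rng.normal(size=(rng.integers(5, 200), 3))
        for squared in (False, True):
            assert chamfer_distance(p1, p2, squared) == pytest.approx(
                brute_chamfer(p1, p2, squared), abs=1e-9)

    def test_symmetry(self, rng):
        p1, p2 = rng.normal(size=(40, 3)), rng.normal(size=(25, 3))
        assert chamfer_distance(p1, p2) == chamfer_distance(p2, p1)

    def test_empty_set_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            chamfer_distance(np.empty((0, 3)), rng.normal(size=(5, 3)))


class TestSignalErrors:
    def test_rmse_examples(self):
        assert rmse([1, 1], [1, 1]) == 0.0
        assert rmse([1.0, 0.0], [0.0, 0.0]) == pytest.approx(1 / np.sqrt(2))
        assert rmse(np.full(7, 0.9), np.full(7, 0.4)) == pytest.approx(0.5)

    def test_prd_examples(self):
        assert prd([1, 2, 3], [1, 2, 3]) == 0.0
        x = np.array([2.0, 0.0])
        assert prd(x, np.zeros(2)) == pytest.approx(100.0)
        y = np.array([0.4, 0.3, -0.8])
        assert prd(y, np.zeros(3)) == pytest.approx(100.0)

    def test_prd_zero_energy_rejected(self):
        with pytest.raises(ValueError, match="zero-energy"):
            prd(np.zeros(5), np.ones(5))


class TestMMD:
    def test_identical_constant_samples_give_zero(self):
        x = np.ones((4, 3))
        assert mmd(x, x, bandwidth=1.0) == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_triple_sum_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(50, 4))
        y = rng.normal(loc=0.5, size=(50, 4))
        h = 1.3
        assert mmd(x, y, bandwidth=h) == pytest.approx(brute_mmd(x, y, h),
                                                       abs=1e-9)

    def test_separates_shifted_distributions(self):
        hits = 0
        for rep in range(100):
            rng = np.random.default_rng(1000 + rep)
            x = rng.normal(size=(200, 4))
            y = rng.normal(loc=3.0, size=(200, 4))
            x2 = rng.normal(size=(200, 4))
            if mmd(x, y, bandwidth=2.0) > mmd(x, x2, bandwidth=2.0):
                hits += 1
        assert hits >= 95

    def test_small_sample_and_bad_bandwidth_rejected(self, rng):
        with pytest.raises(ValueError, match="two vectors"):
            mmd(rng.normal(size=(1, 3)), rng.normal(size=(5, 3)))
        with pytest.raises(ValueError, match="bandwidth"):
            mmd(rng.normal(size=(5, 3)), rng.normal(size=(5, 3)), bandwidth=0.0)


def ellipsoid_shell(rng, semi, n):
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v * np.asarray(semi)


class TestVolumes:
    def test_ellipsoid_volume_within_5_percent(self, rng):
        pts = ellipsoid_shell(rng, (30, 30, 50), 2000)
        analytic = 4 / 3 * np.pi * 30 * 30 * 50 / 1000  # ~188.5 ml
        assert cavity_volume(pts) == pytest.approx(analytic, rel=0.05)

    def test_error_decreases_with_point_count(self, rng):
        analytic = 4 / 3 * np.pi * 30 * 30 * 50 / 1000
        errs = []
        for n in (500, 2000, 8000):
            pts = ellipsoid_shell(np.random.default_rng(4), (30, 30, 50), n)
            errs.append(abs(cavity_volume(pts) - analytic))
        assert errs[0] > errs[1] > errs[2]

    def test_scaling_law(self, rng):
        pts = ellipsoid_shell(rng, (20, 25, 40), 1500)
        v1 = cavity_volume(pts)
        v2 = cavity_volume(pts * 2.0)
        assert v2 == pytest.approx(8 * v1, rel=1e-9)

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(ValueError):
            cavity_volume(np.zeros((3, 3)))

    def test_alpha_shape_matches_hull_for_convex_shell(self, rng):
        pts = ellipsoid_shell(rng, (30, 30, 40), 1500)
        hull = cavity_volume(pts)
        alpha = cavity_volume(pts, method="alpha_shape", alpha=60.0)
        assert alpha == pytest.approx(hull, rel=0.02)


class TestMassAndFunction:
    def test_mass_arithmetic(self, rng):
        # epi/endo spheres with known volumes: r=36.28 -> ~200 ml, r=28.79 -> ~100 ml
        epi = ellipsoid_shell(rng, [36.2783] * 3, 4000)
        endo = ellipsoid_shell(rng, [28.7941] * 3, 4000)
        assert lv_mass(epi, endo) == pytest.approx(105.0, rel=0.02)
        assert lv_mass(epi, endo, density_g_per_ml=1.0) == pytest.approx(
            100.0, rel=0.02)

    def test_epi_inside_endo_rejected(self, rng):
        shell = ellipsoid_shell(rng, (30, 30, 30), 500)
        with pytest.raises(ValueError, match="wall volume"):
            lv_mass(shell, shell * 1.1)

    def test_gold_standard_lv_identities(self):
        # printed population means: EDV 141 ml, ESV 59 ml
        assert stroke_volume(141, 59) == 82
        assert ejection_fraction(141, 59) == pytest.approx(58.156, abs=1e-3)
        assert round(ejection_fraction(141, 59)) == 58

    def test_gold_standard_rv_identities(self):
        assert stroke_volume(170, 78) == 92
        assert ejection_fraction(170, 78) == pytest.approx(54.12, abs=0.01)

    def test_zero_stroke_volume(self):
        assert stroke_volume(100, 100) == 0
        assert ejection_fraction(100, 100) == 0

    def test_nonpositive_edv_rejected(self):
        with pytest.raises(ValueError, match="EDV"):
            stroke_volume(0, 0)


class TestClinicalSummary:
    @pytest.fixture()
    def record_pair(self):
        cfg = GeneratorConfig(n_points_per_class=300, surface_jitter=0.0)
        f = SubjectFactors()
        ed = generate_anatomy(f, Phase.ED, 300, 0, cfg)
        es = generate_anatomy(f, Phase.ES, 300, 0, cfg)
        return ed, es

    def test_identical_subjects_have_zero_sd(self, record_pair):
        summary = clinical_summary([record_pair, record_pair])
        for mean, sd in summary.values():
            assert sd == pytest.approx(0.0, abs=1e-9)

    def test_sv_is_edv_minus_esv_exactly(self, record_pair):
        m = clinical_metrics_for_record(*record_pair)
        assert m.lv_sv == m.lv_edv - m.lv_esv
        assert m.rv_sv == m.rv_edv - m.rv_esv
        assert 0 <= m.lv_ef < 100 and 0 <= m.rv_ef < 100


class TestCombinedRepresentation:
    def _population(self, rng, n=40, length=50):
        from cardiovae.metrics import ClinicalMetrics
        mets, ecgs = [], []
        for _ in range(n):
            vals = rng.uniform(50, 150, size=9)
            mets.append(ClinicalMetrics(*vals))
            ecgs.append(ECGTrace(rng.normal(size=length)))
        return mets, ecgs

    def test_identical_subjects_get_identical_vectors(self, rng):
        mets, ecgs = self._population(rng)
        builder = CombinedRepresentationBuilder(mets, ecgs)
        v1 = builder(mets[0], ecgs[0])
        v2 = builder(mets[0], ecgs[0])
        np.testing.assert_array_equal(v1, v2)

    def test_blocks_contribute_equal_total_variance(self, rng):
        mets, ecgs = self._population(rng)
        builder = CombinedRepresentationBuilder(mets, ecgs)
        mat = np.vstack([builder(m, e) for m, e in zip(mets, ecgs)])
        var_clinical = mat[:, :9].var(axis=0, ddof=1).sum()
        var_ecg = mat[:, 9:].var(axis=0, ddof=1).sum()
        assert var_clinical == pytest.approx(var_ecg, rel=1e-6)

    def test_vector_length_is_metrics_plus_ecg(self, rng):
        mets, ecgs = self._population(rng, length=77)
        builder = CombinedRepresentationBuilder(mets, ecgs)
        assert builder(mets[0], ecgs[0]).size == 9 + 77

    def test_zero_variance_metric_rejected(self, rng):
        from cardiovae.metrics import ClinicalMetrics
        mets = [ClinicalMetrics(*np.ones(9))] * 5
        ecgs = [ECGTrace(rng.normal(size=20)) for _ in range(5)]
        with pytest.raises(ValueError, match="zero-variance"):
            CombinedRepresentationBuilder(mets, ecgs)
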
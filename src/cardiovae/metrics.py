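"""Evaluation metrics: Chamfer distance, ECG error measures, MMD, and
mesh-based clinical cardiac metrics (volumes, mass, stroke volume, ejection
fraction), plus the combined anatomy+ECG representation used for
population-level two-sample comparison.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial import ConvexHull, Delaunay, cKDTree

from .structures import (
    AnatomyPointCloud, CLASS_ORDER, ECGTrace, PointClass, SubjectRecord,
    minmax_normalize,
)

__all__ = [
    "chamfer_distance", "rmse", "prd", "mmd", "median_heuristic_bandwidth",
    "cavity_volume", "alpha_shape_volume", "lv_mass", "stroke_volume",
    "ejection_fraction", "ClinicalMetrics", "clinical_metrics_for_record",
    "clinical_summary", "combined_representation", "CombinedRepresentationBuilder",
    "MYOCARDIAL_DENSITY_G_PER_ML",
]

MYOCARDIAL_DENSITY_G_PER_ML = 1.05


# ---------------------------------------------------------------------------
# point-set and signal distances
# ---------------------------------------------------------------------------

def _nn_dists(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """For each row of a, the Euclidean distance to the nearest row of b."""
    if a.shape[0] * b.shape[0] <= 250_000:
        d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)
        return np.sqrt(d2.min(axis=1))
    d, _ = cKDTree(b).query(a)
    return d


def chamfer_distance(p1: np.ndarray, p2: np.ndarray, squared: bool = False) -> float:
    """Symmetric mean nearest-neighbour distance between two point sets.

    ``CD = 1/2 ( mean_x min_y d(x,y) + mean_y min_x d(y,x) )`` with
    d Euclidean (mm) or squared Euclidean (mm^2) when ``squared``.
    """
    p1 = np.asarray(p1, dtype=np.float64)
    p2 = np.asarray(p2, dtype=np.float64)
    if p1.size == 0 or p2.size == 0:
        raise ValueError("Chamfer distance of an empty point set is undefined")
    d12 = _nn_dists(p1, p2)
    d21 = _nn_dists(p2, p1)
    if squared:
        return 0.5 * float((d12 ** 2).mean() + (d21 ** 2).mean())
    return 0.5 * float(d12.mean() + d21.mean())


def rmse(x: np.ndarray, y: np.ndarray) -> float:
    """Root mean squared error between two equal-length signals."""
    x = np.asarray(x, dtype=np.float64).reshape(-1)
    y = np.asarray(y, dtype=np.float64).reshape(-1)
    if x.size != y.size:
        raise ValueError("rmse: length mismatch")
    return float(np.sqrt(((x - y) ** 2).mean()))


def prd(x: np.ndarray, y: np.ndarray) -> float:
    """Percentage root mean squared distance.

    ``sqrt( sum (x-y)^2 / sum x^2 ) * 100`` — the energy of the first
    argument normalises the error.
    """
    x = np.asarray(x, dtype=np.float64).reshape(-1)
    y = np.asarray(y, dtype=np.float64).reshape(-1)
    if x.size != y.size:
        raise ValueError("prd: length mismatch")
    energy = float((x ** 2).sum())
    if energy <= 0:
        raise ValueError("prd: zero-energy reference signal")
    return float(np.sqrt(((x - y) ** 2).sum() / energy) * 100.0)


def ecg_reconstruction_errors(pred: ECGTrace, target: ECGTrace) -> tuple[float, float]:
    """(RMSE, PRD) after per-signal min-max normalization of both traces."""
    xp = minmax_normalize(pred).samples
    xt = minmax_normalize(target).samples
    return rmse(xp, xt), prd(xp, xt)


def median_heuristic_bandwidth(x: np.ndarray, y: np.ndarray) -> float:
    """Median pairwise distance over the pooled sample (Gaussian-kernel h)."""
    pooled = np.vstack([x, y])
    d2 = ((pooled[:, None, :] - pooled[None, :, :]) ** 2).sum(axis=2)
    med = np.median(np.sqrt(d2[np.triu_indices(pooled.shape[0], k=1)]))
    return float(med) if med > 0 else 1.0


def mmd(x: np.ndarray, y: np.ndarray, bandwidth: float | None = None,
        unbiased: bool = True) -> float:
    """Gaussian-kernel maximum mean discrepancy (square-rooted).

    Uses ``K(a, b) = exp(-||a-b||^2 / (2 h^2))``.  The default U-statistic
    estimator (diagonal terms excluded, ``1/(n(n-1))`` normalisation) is
    unbiased but can dip below zero for close distributions, in which case it
    is clamped to zero before the square root.  ``unbiased=False`` selects the
    biased V-statistic, which is strictly nonnegative — useful when a ratio
    of MMD values is needed and the unbiased same-distribution baseline would
    clamp to zero.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n, m = x.shape[0], y.shape[0]
    if n < 2 or m < 2:
        raise ValueError("mmd requires at least two vectors per sample")
    if bandwidth is None:
        bandwidth = median_heuristic_bandwidth(x, y)
    if bandwidth <= 0:
        raise ValueError("mmd bandwidth must be positive")
    h2 = 2.0 * bandwidth ** 2

    def gram(a, b):
        d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)
        return np.exp(-d2 / h2)

    kxx = gram(x, x)
    kyy = gram(y, y)
    kxy = gram(x, y)
    if unbiased:
        sxx = (kxx.sum() - np.trace(kxx)) / (n * (n - 1))
        syy = (kyy.sum() - np.trace(kyy)) / (m * (m - 1))
    else:
        sxx = kxx.mean()
        syy = kyy.mean()
    sxy = kxy.mean()
    return float(np.sqrt(max(sxx + syy - 2.0 * sxy, 0.0)))


# ---------------------------------------------------------------------------
# mesh-based clinical metrics
# ---------------------------------------------------------------------------

def cavity_volume(points: np.ndarray, method: str = "convex_hull",
                  alpha: float | None = None) -> float:
    """Volume (ml) of the watertight surface meshed from a point set.

    ``convex_hull`` is exact for the generator's convex shells; the
    ``alpha_shape`` option handles concave clouds (Delaunay tetrahedra with
    circumradius below ``alpha`` mm).
    """
    points = np.asarray(points, dtype=np.float64)
    if points.shape[0] < 4:
        raise ValueError("need at least 4 points to mesh a volume")
    if method == "convex_hull":
        try:
            hull = ConvexHull(points)
        except Exception as exc:
            raise ValueError(f"degenerate geometry, meshing failed: {exc}") from exc
        return float(hull.volume) / 1000.0
    if method == "alpha_shape":
        if alpha is None:
            raise ValueError("alpha_shape meshing needs an alpha radius (mm)")
        return alpha_shape_volume(points, alpha)
    raise ValueError(f"unknown meshing method {method!r}")


def alpha_shape_volume(points: np.ndarray, alpha: float) -> float:
    """Volume (ml) of the alpha-complex: Delaunay tetrahedra with
    circumradius < alpha."""
    points = np.asarray(points, dtype=np.float64)
    try:
        tri = Delaunay(points)
    except Exception as exc:
        raise ValueError(f"degenerate geometry, meshing failed: {exc}") from exc
    tets = points[tri.simplices]          # (T, 4, 3)
    a, b, c, d = tets[:, 0], tets[:, 1], tets[:, 2], tets[:, 3]
    ba, ca, da = b - a, c - a, d - a
    vol6 = np.einsum("ij,ij->i", ba, np.cross(ca, da))
    # circumradius via the standard linear solve per tetrahedron
    sq = np.stack([(ba * ba).sum(1), (ca * ca).sum(1), (da * da).sum(1)], axis=1)
    mats = np.stack([ba, ca, da], axis=1)                      # (T, 3, 3)
    good = np.abs(vol6) > 1e-12
    radius = np.full(tets.shape[0], np.inf)
    if good.any():
        centers = np.linalg.solve(mats[good], (0.5 * sq[good])[:, :, None])[:, :, 0]
        radius[good] = np.linalg.norm(centers, axis=1)
    keep = radius < alpha
    return float(np.abs(vol6[keep]).sum() / 6.0) / 1000.0


def lv_mass(epi_points: np.ndarray, endo_points: np.ndarray,
            density_g_per_ml: float = MYOCARDIAL_DENSITY_G_PER_ML,
            method: str = "convex_hull", alpha: float | None = None) -> float:
    """Myocardial mass (g): wall volume (epi minus endo) times density."""
    v_epi = cavity_volume(epi_points, method=method, alpha=alpha)
    v_endo = cavity_volume(endo_points, method=method, alpha=alpha)
    wall = v_epi - v_endo
    if wall <= 0:
        raise ValueError("nonpositive wall volume: epi must enclose endo")
    return wall * density_g_per_ml


def stroke_volume(edv: float, esv: float) -> float:
    """SV = EDV - ESV (ml)."""
    if edv <= 0:
        raise ValueError("EDV must be positive")
    return edv - esv


def ejection_fraction(edv: float, esv: float) -> float:
    """EF = (EDV - ESV) / EDV * 100 (percent)."""
    return stroke_volume(edv, esv) / edv * 100.0


@dataclasses.dataclass
class ClinicalMetrics:
    """Per-subject biventricular anatomy and function metrics."""

    lv_edv: float
    lv_esv: float
    rv_edv: float
    rv_esv: float
    lv_mass: float
    lv_sv: float
    rv_sv: float
    lv_ef: float
    rv_ef: float

    NAMES = ("lv_edv", "lv_esv", "rv_edv", "rv_esv", "lv_mass",
             "lv_sv", "rv_sv", "lv_ef", "rv_ef")

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in self.NAMES], dtype=np.float64)


def clinical_metrics_for_record(ed: AnatomyPointCloud, es: AnatomyPointCloud,
                                method: str = "convex_hull",
                                alpha: float | None = None) -> ClinicalMetrics:
    lv_edv = cavity_volume(ed.points_by_class[PointClass.LV_ENDO], method, alpha)
    lv_esv = cavity_volume(es.points_by_class[PointClass.LV_ENDO], method, alpha)
    rv_edv = cavity_volume(ed.points_by_class[PointClass.RV_ENDO], method, alpha)
    rv_esv = cavity_volume(es.points_by_class[PointClass.RV_ENDO], method, alpha)
    mass = lv_mass(ed.points_by_class[PointClass.LV_EPI],
                   ed.points_by_class[PointClass.LV_ENDO],
                   method=method, alpha=alpha)
    return ClinicalMetrics(
        lv_edv=lv_edv, lv_esv=lv_esv, rv_edv=rv_edv, rv_esv=rv_esv,
        lv_mass=mass,
        lv_sv=stroke_volume(lv_edv, lv_esv),
        rv_sv=stroke_volume(rv_edv, rv_esv),
        lv_ef=ejection_fraction(lv_edv, lv_esv),
        rv_ef=ejection_fraction(rv_edv, rv_esv),
    )


def clinical_summary(population, sd: str = "sample") -> dict[str, tuple[float, float]]:
    """Mean (±SD) of each clinical metric across a population.

    ``population`` holds :class:`SubjectRecord` objects or (ed, es) cloud
    pairs.  Ratio metrics (EF) are computed per subject and then averaged.
    SD is the sample SD (n-1) by default; pass ``sd="population"`` for /n.
    """
    rows = []
    for item in population:
        if isinstance(item, SubjectRecord):
            rows.append(clinical_metrics_for_record(item.ed, item.es).as_vector())
        else:
            ed, es = item
            rows.append(clinical_metrics_for_record(ed, es).as_vector())
    if not rows:
        raise ValueError("empty population")
    mat = np.vstack(rows)
    ddof = 1 if (sd == "sample" and mat.shape[0] > 1) else 0
    means = mat.mean(axis=0)
    sds = mat.std(axis=0, ddof=ddof)
    return {name: (float(means[i]), float(sds[i]))
            for i, name in enumerate(ClinicalMetrics.NAMES)}


# ---------------------------------------------------------------------------
# combined anatomy + ECG representation
# ---------------------------------------------------------------------------

class CombinedRepresentationBuilder:
    """Concatenate standardized clinical metrics with the ECG samples.

    Clinical metrics are z-scored against a reference population, then the
    metric block is rescaled so that its total variance equals that of the
    ECG block — giving anatomy and electrophysiology balanced influence in
    population two-sample statistics.
    """

    def __init__(self, reference_metrics: list[ClinicalMetrics],
                 reference_ecgs: list[ECGTrace]):
        mat = np.vstack([m.as_vector() for m in reference_metrics])
        self.metric_mean = mat.mean(axis=0)
        self.metric_sd = mat.std(axis=0, ddof=1)
        if np.any(self.metric_sd <= 0):
            bad = [ClinicalMetrics.NAMES[i]
                   for i in np.where(self.metric_sd <= 0)[0]]
            raise ValueError(f"zero-variance reference metric(s): {bad}")
        ecg_mat = np.vstack([t.samples for t in reference_ecgs])
        ecg_var = ecg_mat.var(axis=0, ddof=1).sum()
        z = (mat - self.metric_mean) / self.metric_sd
        metric_var = z.var(axis=0, ddof=1).sum()
        self.block_scale = float(np.sqrt(ecg_var / metric_var))

    def __call__(self, metrics: ClinicalMetrics, ecg: ECGTrace) -> np.ndarray:
        z = (metrics.as_vector() - self.metric_mean) / self.metric_sd
        return np.concatenate([z * self.block_scale, ecg.samples])


def combined_representation(subject_metrics: ClinicalMetrics, ecg: ECGTrace,
                            builder: CombinedRepresentationBuilder) -> np.ndarray:
    return builder(subject_metrics, ecg)
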
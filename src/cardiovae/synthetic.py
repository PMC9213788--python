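"""Synthetic paired biventricular anatomy + single-beat ECG populations.

The generator stands in for a cardiac MRI + ECG cohort: each virtual subject
is defined by a small set of latent *factors* (overall size, long-axis
elongation, basal tilt, wall thickness, systolic contraction, ECG wave
amplitudes/widths) that jointly shape two labeled 3D point clouds (end
diastole and end systole) and one lead II heartbeat.  Because the same
factors drive both domains, the population carries genuine cross-domain
structure — e.g. heart size correlates with R amplitude, contraction with
T amplitude — which is exactly what a shared-latent multi-branch VAE is
supposed to discover.

Geometry is analytic: the LV endocardium is a basally truncated prolate
ellipsoid shell, the LV epicardium the same shell offset outward by the wall
thickness, and the RV endocardium a clipped larger ellipsoid cap attached
laterally (all three are convex, so convex-hull volumes are exact oracles).
Default dimensions are calibrated so that a healthy population reproduces
textbook biventricular volumes (LV EDV ~141 ml, ESV ~59 ml, mass ~102 g,
RV EDV ~170 ml, ESV ~78 ml; ejection fractions near 58/55%).

Surfaces are sampled on a quasi-uniform Fibonacci lattice with small Gaussian
jitter, mimicking the near-regular vertex spacing of mesh-based surface
reconstructions rather than Poisson scatter.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np

from .structures import (
    AnatomyPointCloud, CLASS_ORDER, ECGTrace, Phase, PointClass, SubjectRecord,
    standardize_ecg,
)

__all__ = [
    "SubjectFactors", "GeneratorConfig", "sample_factors", "generate_anatomy",
    "generate_ecg", "generate_population", "mean_nn_spacing",
]

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclasses.dataclass
class SubjectFactors:
    """Ground-truth per-subject generative factors.

    ``contraction`` is the ED->ES linear scale of the endocardial cavity
    (smaller = stronger contraction; LV EF = 1 - contraction^3).
    """

    size: float = 1.0
    elongation: float = 1.0
    tilt: float = 0.0              # degrees, about the y axis
    wall_thickness: float = 7.5    # mm
    contraction: float = 0.75
    r_amp: float = 1.0
    p_amp: float = 1.0
    t_amp: float = 1.0
    rs_width: float = 1.0
    disease: bool = False

    def __post_init__(self):
        if self.size <= 0:
            raise ValueError("size must be positive")
        if not (0.0 < self.contraction < 1.0):
            raise ValueError("contraction must lie in (0, 1)")
        if self.wall_thickness <= 0:
            raise ValueError("wall_thickness must be positive")

    def as_vector(self) -> np.ndarray:
        return np.array([self.size, self.elongation, self.tilt,
                         self.wall_thickness, self.contraction, self.r_amp,
                         self.p_amp, self.t_amp, self.rs_width], dtype=np.float64)

    FACTOR_NAMES = ("size", "elongation", "tilt", "wall_thickness",
                    "contraction", "r_amp", "p_amp", "t_amp", "rs_width")


@dataclasses.dataclass
class GeneratorConfig:
    """All knobs of the virtual cohort.

    Factor distributions are Gaussian with the means/SDs below; the disease
    shift is added to the means of the diseased subgroup (a dilated,
    poorly-contracting phenotype with flattened T waves and broadened QRS).
    """

    n_points_per_class: int = 12000
    ecg_length: int = 400
    seed: int = 0

    # healthy factor means and SDs
    factor_means: dict = dataclasses.field(default_factory=lambda: {
        "size": 1.0, "elongation": 1.0, "tilt": 0.0, "wall_thickness": 7.5,
        "contraction": 0.75, "r_amp": 1.0, "p_amp": 1.0, "t_amp": 1.0,
        "rs_width": 1.0})
    factor_sds: dict = dataclasses.field(default_factory=lambda: {
        "size": 0.08, "elongation": 0.06, "tilt": 5.0, "wall_thickness": 0.8,
        "contraction": 0.03, "r_amp": 0.1, "p_amp": 0.12, "t_amp": 0.15,
        "rs_width": 0.1})
    disease_shift: dict = dataclasses.field(default_factory=lambda: {
        "size": 0.18, "contraction": 0.07, "wall_thickness": -1.0,
        "t_amp": -0.35, "rs_width": 0.25})

    # cross-domain couplings (the structure the VAE must learn)
    coupling_size_to_r_amp: float = 2.0
    coupling_contraction_to_t_amp: float = 3.0

    # geometry (mm, for size = elongation = 1)
    lv_short_axis: float = 30.0       # LV endocardial short semi-axis a
    lv_axis_ratio: float = 1.8        # long/short semi-axis ratio b/a
    base_cut: float = 0.25            # basal truncation plane at z = base_cut*b
    rv_semi_axes: tuple = (45.0, 40.0, 55.0)
    rv_center_x: float = 33.6
    rv_clip_u: float = 0.12           # septal clip plane as fraction of RV x semi-axis
    rv_scale: float = 1.135           # global RV scale, calibrated to RV EDV ~170 ml
    rv_es_scale_ratio: float = 1.02   # RV contraction = contraction * this
    epi_base_offset: float = 0.0

    # noise
    surface_jitter: float = 0.4       # mm, isotropic Gaussian on every point
    ecg_noise: float = 0.01           # additive noise before standardization

    # ECG morphology: fractional positions / widths / base amplitudes
    wave_positions: dict = dataclasses.field(default_factory=lambda: {
        "P": 0.15, "Q": 0.38, "R": 0.42, "S": 0.46, "T": 0.72})
    wave_widths: dict = dataclasses.field(default_factory=lambda: {
        "P": 0.030, "Q": 0.012, "R": 0.014, "S": 0.012, "T": 0.050})
    wave_amplitudes: dict = dataclasses.field(default_factory=lambda: {
        "P": 0.15, "Q": -0.08, "R": 1.0, "S": -0.20, "T": 0.35})

    def __post_init__(self):
        if self.n_points_per_class < 8:
            raise ValueError("n_points_per_class must be >= 8")
        for k, v in self.factor_sds.items():
            if v < 0:
                raise ValueError(f"factor SD for {k!r} must be >= 0")


def _draw_factors(rng: np.random.Generator, config: GeneratorConfig,
                  diseased: bool) -> SubjectFactors:
    vals = {}
    for name in SubjectFactors.FACTOR_NAMES:
        mu = config.factor_means[name]
        if diseased:
            mu = mu + config.disease_shift.get(name, 0.0)
        vals[name] = rng.normal(mu, config.factor_sds[name])
    # cross-domain couplings, applied after the independent draws
    vals["r_amp"] += config.coupling_size_to_r_amp * (
        vals["size"] - config.factor_means["size"])
    vals["t_amp"] += config.coupling_contraction_to_t_amp * (
        config.factor_means["contraction"] - vals["contraction"])
    # keep factors physical
    vals["size"] = max(vals["size"], 0.5)
    vals["elongation"] = float(np.clip(vals["elongation"], 0.6, 1.6))
    vals["wall_thickness"] = max(vals["wall_thickness"], 3.0)
    vals["contraction"] = float(np.clip(vals["contraction"], 0.55, 0.95))
    vals["rs_width"] = max(vals["rs_width"], 0.4)
    return SubjectFactors(disease=diseased, **vals)


def sample_factors(n: int, config: GeneratorConfig, diseased: bool = False,
                   index_offset: int = 0) -> list[SubjectFactors]:
    """Draw ``n`` subjects' factors; subject ``i`` uses seed ``config.seed + i``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return [
        _draw_factors(np.random.default_rng(config.seed + index_offset + i),
                      config, diseased)
        for i in range(n)
    ]


def _fibonacci_band(n: int, u_lo: float, u_hi: float, phi0: float) -> np.ndarray:
    """n quasi-uniform (u, phi) pairs with u in [u_lo, u_hi] (area-uniform on a sphere)."""
    i = np.arange(n)
    u = u_lo + (u_hi - u_lo) * (i + 0.5) / n
    phi = phi0 + i * _GOLDEN_ANGLE
    return np.column_stack([u, phi])


def _ellipsoid_shell(n: int, semi: np.ndarray, u_max: float,
                     phi0: float) -> np.ndarray:
    """Points on an ellipsoid (z-parameterised), truncated to z/c <= u_max."""
    up = _fibonacci_band(n, -1.0, u_max, phi0)
    u, phi = up[:, 0], up[:, 1]
    r = np.sqrt(np.maximum(1.0 - u * u, 0.0))
    return np.column_stack([semi[0] * r * np.cos(phi),
                            semi[1] * r * np.sin(phi),
                            semi[2] * u])


def _rv_cap(n: int, semi: np.ndarray, center_x: float, clip_u: float,
            base_u: float, phi0: float) -> np.ndarray:
    """Lateral cap of an ellipsoid: x'/A >= clip_u, clipped to z/C <= base_u."""
    # parameterise around the x axis, oversample, filter the basal cut,
    # then take an even deterministic subsequence of exactly n points
    m = max(int(np.ceil(2.2 * n)), n + 8)
    up = _fibonacci_band(m, clip_u, 1.0, phi0)
    u, psi = up[:, 0], up[:, 1]
    r = np.sqrt(np.maximum(1.0 - u * u, 0.0))
    pts = np.column_stack([semi[0] * u + center_x,
                           semi[1] * r * np.cos(psi),
                           semi[2] * r * np.sin(psi)])
    keep = pts[:, 2] <= base_u * semi[2]
    pts = pts[keep]
    if pts.shape[0] < n:  # pragma: no cover - generous oversampling
        raise RuntimeError("RV cap oversampling insufficient")
    idx = np.floor(np.linspace(0, pts.shape[0] - 1, n)).astype(int)
    return pts[idx]


def _rotation_y(deg: float) -> np.ndarray:
    th = np.deg2rad(deg)
    c, s = np.cos(th), np.sin(th)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def generate_anatomy(factors: SubjectFactors, phase: Phase | str,
                     n_points_per_class: int,
                     rng: np.random.Generator | int | None = None,
                     config: GeneratorConfig | None = None) -> AnatomyPointCloud:
    """Build the labeled biventricular shell for one phase of one subject."""
    phase = Phase(phase)
    cfg = config or GeneratorConfig(n_points_per_class=n_points_per_class)
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    elif rng is None:
        rng = np.random.default_rng(0)

    s, e = factors.size, factors.elongation
    a = cfg.lv_short_axis * s
    b = cfg.lv_short_axis * cfg.lv_axis_ratio * e * s
    w = factors.wall_thickness
    c = factors.contraction
    c_epi = 0.5 * (1.0 + c)
    c_rv = min(c * cfg.rv_es_scale_ratio, 0.995)

    if phase is Phase.ED:
        endo_semi = np.array([a, a, b])
        epi_semi = endo_semi + w
        z_base = cfg.base_cut * b
        rv_semi = np.array(cfg.rv_semi_axes) * cfg.rv_scale * s * np.array([1.0, 1.0, e])
        rv_cx = cfg.rv_center_x * cfg.rv_scale * s
    else:
        endo_semi = np.array([a, a, b]) * c
        epi_semi = (np.array([a, a, b]) + w) * c_epi
        z_base = cfg.base_cut * b * c
        rv_semi = (np.array(cfg.rv_semi_axes) * cfg.rv_scale * s
                   * np.array([1.0, 1.0, e]) * c_rv)
        rv_cx = cfg.rv_center_x * cfg.rv_scale * s

    phi0 = rng.uniform(0.0, 2.0 * np.pi)
    n = n_points_per_class
    endo = _ellipsoid_shell(n, endo_semi, min(z_base / endo_semi[2], 0.95), phi0)
    epi = _ellipsoid_shell(n, epi_semi, min(z_base / epi_semi[2], 0.95),
                           phi0 + 1.0)
    rv = _rv_cap(n, rv_semi, rv_cx, cfg.rv_clip_u, cfg.base_cut, phi0 + 2.0)

    pts = {PointClass.LV_ENDO: endo, PointClass.LV_EPI: epi,
           PointClass.RV_ENDO: rv}
    if cfg.surface_jitter > 0:
        for cls in CLASS_ORDER:
            pts[cls] = pts[cls] + rng.normal(0.0, cfg.surface_jitter,
                                             pts[cls].shape)
    else:
        for cls in CLASS_ORDER:  # keep the rng stream aligned across jitter settings
            rng.normal(0.0, 1.0, pts[cls].shape)
    rot = _rotation_y(factors.tilt).T
    pts = {cls: p @ rot for cls, p in pts.items()}
    return AnatomyPointCloud(pts, phase)


def generate_ecg(factors: SubjectFactors, length: int,
                 rng: np.random.Generator | int | None = None,
                 config: GeneratorConfig | None = None) -> ECGTrace:
    """Sum of five Gaussian deflections (P, Q, R, S, T), noise, then z-scoring."""
    if length < 50:
        raise ValueError("ECG length must be >= 50")
    cfg = config or GeneratorConfig(ecg_length=length)
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    elif rng is None:
        rng = np.random.default_rng(0)
    t = (np.arange(length) + 0.5) / length
    amp_scale = {"P": factors.p_amp, "Q": factors.r_amp, "R": factors.r_amp,
                 "S": factors.r_amp, "T": factors.t_amp}
    width_scale = {"P": 1.0, "Q": factors.rs_width, "R": factors.rs_width,
                   "S": factors.rs_width, "T": 1.0}
    x = np.zeros(length)
    for wave, pos in cfg.wave_positions.items():
        amp = cfg.wave_amplitudes[wave] * amp_scale[wave]
        width = cfg.wave_widths[wave] * width_scale[wave]
        x += amp * np.exp(-0.5 * ((t - pos) / width) ** 2)
    if cfg.ecg_noise > 0:
        x = x + rng.normal(0.0, cfg.ecg_noise, length)
    return standardize_ecg(ECGTrace(x))


def generate_subject(factors: SubjectFactors, config: GeneratorConfig,
                     subject_seed: int, subject_id: str) -> SubjectRecord:
    rng = np.random.default_rng(subject_seed)
    ed = generate_anatomy(factors, Phase.ED, config.n_points_per_class, rng, config)
    es = generate_anatomy(factors, Phase.ES, config.n_points_per_class, rng, config)
    ecg = generate_ecg(factors, config.ecg_length, rng, config)
    return SubjectRecord(ed=ed, es=es, ecg=ecg, disease=factors.disease,
                         truth_factors=factors, subject_id=subject_id)


def generate_population(n_healthy: int, n_diseased: int,
                        config: GeneratorConfig) -> list[SubjectRecord]:
    """A fully deterministic cohort: pure function of (config, counts)."""
    if n_healthy + n_diseased < 1:
        raise ValueError("population must contain at least one subject")
    records: list[SubjectRecord] = []
    healthy = sample_factors(n_healthy, config, diseased=False) if n_healthy else []
    diseased = (sample_factors(n_diseased, config, diseased=True,
                               index_offset=n_healthy) if n_diseased else [])
    for i, factors in enumerate(healthy + diseased):
        # geometry/noise stream offset so it is independent of the factor draw
        records.append(generate_subject(factors, config,
                                        subject_seed=config.seed + 1_000_003 + i,
                                        subject_id=f"S{i:05d}"))
    return records


def mean_nn_spacing(clouds: list[AnatomyPointCloud]) -> float:
    """Mean distance from each point to its nearest same-class neighbour.

    This is the sampling resolution of the generated surfaces: reconstruction
    errors below it are at the data's own resolution, mirroring how image
    based surface models are judged against voxel size.
    """
    from scipy.spatial import cKDTree

    dists = []
    for pc in clouds:
        for cls in CLASS_ORDER:
            pts = pc.points_by_class[cls]
            d, _ = cKDTree(pts).query(pts, k=2)
            dists.append(d[:, 1].mean())
    return float(np.mean(dists))
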
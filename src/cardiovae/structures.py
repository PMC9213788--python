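"""Core domain types: labeled anatomy point clouds, ECG traces, subject records.

Coordinates are millimetres throughout.  Anatomy point clouds carry exactly
three substructure classes — LV endocardium, LV epicardium, RV endocardium —
stored as per-class coordinate blocks in a fixed canonical order so that loss
and metric computations align classes without bookkeeping.  ECG traces are
fixed-length single-beat lead II sample vectors with an explicit normalization
state (raw, z-scored, or min-max scaled).
"""

from __future__ import annotations

import dataclasses
import enum
from typing import Optional

import numpy as np

__all__ = [
    "PointClass", "Phase", "Normalization", "AnatomyPointCloud", "ECGTrace",
    "SubjectRecord", "DatasetSplit", "standardize_ecg", "minmax_normalize",
    "split_dataset", "CLASS_ORDER",
]


class PointClass(enum.IntEnum):
    LV_ENDO = 0
    LV_EPI = 1
    RV_ENDO = 2


CLASS_ORDER: tuple[PointClass, ...] = (
    PointClass.LV_ENDO, PointClass.LV_EPI, PointClass.RV_ENDO)


class Phase(str, enum.Enum):
    ED = "ED"
    ES = "ES"


class Normalization(str, enum.Enum):
    RAW = "RAW"
    STANDARDIZED = "STANDARDIZED"
    MINMAX = "MINMAX"


@dataclasses.dataclass
class AnatomyPointCloud:
    """One cardiac phase of a biventricular surface as labeled 3D points."""

    points_by_class: dict[PointClass, np.ndarray]
    phase: Phase

    def __post_init__(self):
        if set(self.points_by_class) != set(CLASS_ORDER):
            raise ValueError(
                f"anatomy cloud must contain exactly the classes {[c.name for c in CLASS_ORDER]}")
        cleaned = {}
        n0 = None
        for cls in CLASS_ORDER:
            pts = np.asarray(self.points_by_class[cls], dtype=np.float64)
            if pts.ndim != 2 or pts.shape[1] != 3:
                raise ValueError(f"class {cls.name}: points must be (n, 3)")
            if pts.shape[0] == 0:
                raise ValueError(f"class {cls.name}: empty class block")
            if not np.all(np.isfinite(pts)):
                raise ValueError(f"class {cls.name}: non-finite coordinates")
            if n0 is None:
                n0 = pts.shape[0]
            cleaned[cls] = pts
        self.points_by_class = cleaned
        self.phase = Phase(self.phase)

    @property
    def n_points_per_class(self) -> dict[PointClass, int]:
        return {c: p.shape[0] for c, p in self.points_by_class.items()}

    def stacked(self) -> np.ndarray:
        """All points as (N, 4) rows of (x, y, z, class id), canonical order."""
        blocks = []
        for cls in CLASS_ORDER:
            pts = self.points_by_class[cls]
            lab = np.full((pts.shape[0], 1), float(cls))
            blocks.append(np.hstack([pts, lab]))
        return np.vstack(blocks)

    def translated(self, offset: np.ndarray) -> "AnatomyPointCloud":
        return AnatomyPointCloud(
            {c: p + np.asarray(offset, dtype=np.float64) for c, p in self.points_by_class.items()},
            self.phase)

    def centroid(self) -> np.ndarray:
        return np.vstack(list(self.points_by_class.values())).mean(axis=0)


@dataclasses.dataclass
class ECGTrace:
    """Fixed-length single-beat lead II trace with a normalization tag."""

    samples: np.ndarray
    normalization: Normalization = Normalization.RAW

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64).reshape(-1)
        if self.samples.size == 0:
            raise ValueError("empty ECG trace")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("non-finite ECG samples")
        self.normalization = Normalization(self.normalization)

    def __len__(self) -> int:
        return self.samples.size


@dataclasses.dataclass
class SubjectRecord:
    """Paired bitemporal anatomy and ECG for one subject."""

    ed: AnatomyPointCloud
    es: AnatomyPointCloud
    ecg: ECGTrace
    disease: Optional[bool] = None
    truth_factors: Optional[object] = None  # SubjectFactors for synthetic data
    subject_id: Optional[str] = None

    def __post_init__(self):
        if self.ed.phase is not Phase.ED:
            raise ValueError("record.ed must have phase ED")
        if self.es.phase is not Phase.ES:
            raise ValueError("record.es must have phase ES")


@dataclasses.dataclass
class DatasetSplit:
    train: list[SubjectRecord]
    validation: list[SubjectRecord]
    test: list[SubjectRecord]
    seed: int


def standardize_ecg(trace: ECGTrace) -> ECGTrace:
    """Z-score a trace: subtract the mean, divide by the population SD.

    Idempotent; raises on a constant signal (zero variance).
    """
    x = trace.samples
    sd = x.std()  # population SD (divide by N)
    if sd == 0:
        raise ValueError("cannot standardize a constant ECG trace (zero variance)")
    return ECGTrace((x - x.mean()) / sd, Normalization.STANDARDIZED)


def minmax_normalize(trace: ECGTrace) -> ECGTrace:
    """Affinely map a trace onto [0, 1] (per-signal min-max scaling)."""
    x = trace.samples
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise ValueError("cannot min-max normalize a constant ECG trace (zero range)")
    return ECGTrace((x - lo) / (hi - lo), Normalization.MINMAX)


def _largest_remainder_sizes(n: int, ratios: tuple[float, float, float]) -> list[int]:
    """Integer split sizes summing to n, by the largest-remainder method."""
    exact = [n * r for r in ratios]
    base = [int(np.floor(e)) for e in exact]
    short = n - sum(base)
    remainders = np.array([e - b for e, b in zip(exact, base)])
    for i in np.argsort(-remainders)[:short]:
        base[i] += 1
    return base


def split_dataset(records: list[SubjectRecord],
                  ratios: tuple[float, float, float] = (0.8, 0.05, 0.15),
                  seed: int = 0) -> DatasetSplit:
    """Random disjoint train/validation/test split, deterministic in ``seed``."""
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"split ratios must sum to 1, got {sum(ratios)}")
    if len(records) < 3:
        raise ValueError("need at least 3 records to split")
    sizes = _largest_remainder_sizes(len(records), tuple(ratios))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    i1, i2 = sizes[0], sizes[0] + sizes[1]
    return DatasetSplit(
        train=[records[i] for i in order[:i1]],
        validation=[records[i] for i in order[i1:i2]],
        test=[records[i] for i in order[i2:]],
        seed=seed,
    )
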
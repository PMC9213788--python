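"""Point-cloud branch: multi-class point-set encoder and two-stage decoder.

The encoder is a multi-class point-set network: each point enters as a 4-D
row (x, y, z, class), passes through a shared per-point MLP, is max-pooled
into a global feature which is broadcast back ("unpooled") and concatenated
with the per-point features (skip connection), passed through a second
shared MLP and pooled again — the stacked two-stage design used by point
completion networks.  Max pooling makes the feature exactly invariant to
point order within classes.

The decoder first maps the latent vector through an MLP to a coarse
multi-class cloud (750 points per class at full scale) and then, following
the folding design, deforms a small tiled 2-D grid around every coarse point
conditioned on the latent vector and the class, producing the dense output
(12,000 points per class at full scale).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .nn import MLP, Module, Tensor, concat
from .structures import AnatomyPointCloud, CLASS_ORDER, Phase

__all__ = [
    "AnatomyEncoderConfig", "AnatomyDecoderConfig", "AnatomyPrediction",
    "AnatomyEncoder", "AnatomyDecoder", "prediction_to_cloud",
]

N_CLASSES = 3


@dataclasses.dataclass
class AnatomyEncoderConfig:
    stage1_widths: tuple = (128, 256)
    stage2_widths: tuple = (512, 1024)
    fc_widths: tuple = (512, 256)
    class_encoding: str = "numeric"    # or "onehot"
    class_scale: float = 1.0

    def __post_init__(self):
        for w in (*self.stage1_widths, *self.stage2_widths, *self.fc_widths):
            if w < 1:
                raise ValueError("layer widths must be >= 1")
        if self.class_encoding not in ("numeric", "onehot"):
            raise ValueError("class_encoding must be 'numeric' or 'onehot'")

    @property
    def feature_width(self) -> int:
        return self.fc_widths[-1]


@dataclasses.dataclass
class AnatomyDecoderConfig:
    n_coarse_per_class: int = 750
    grid_side: int = 4
    coarse_widths: tuple = (1024, 1024)
    fold_widths: tuple = (512, 512)
    grid_extent: float = 0.05

    def __post_init__(self):
        if self.n_coarse_per_class < 1 or self.grid_side < 1:
            raise ValueError("decoder sizes must be >= 1")

    @property
    def n_dense_per_class(self) -> int:
        return self.n_coarse_per_class * self.grid_side ** 2


@dataclasses.dataclass
class AnatomyPrediction:
    """Coarse and dense decoder outputs, shaped (B, 3 classes, n, 3)."""

    coarse: Tensor
    dense: Tensor


class AnatomyEncoder(Module):
    def __init__(self, config: AnatomyEncoderConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        in_dim = 3 + (N_CLASSES if config.class_encoding == "onehot" else 1)
        self.stage1 = MLP([in_dim, *config.stage1_widths], rng,
                          final_activation=True)
        w1 = config.stage1_widths[-1]
        self.stage2 = MLP([2 * w1, *config.stage2_widths], rng,
                          final_activation=True)
        self.fc = MLP([config.stage2_widths[-1], *config.fc_widths], rng)

    def _embed_input(self, points: np.ndarray) -> np.ndarray:
        """(B, N, 4) float rows -> network input with the configured class encoding."""
        cfg = self.config
        if cfg.class_encoding == "numeric":
            out = points.astype(np.float32, copy=True)
            out[:, :, 3] *= cfg.class_scale
            return out
        onehot = np.eye(N_CLASSES, dtype=np.float32)[points[:, :, 3].astype(int)]
        return np.concatenate([points[:, :, :3].astype(np.float32), onehot], axis=2)

    def forward(self, points: np.ndarray | Tensor) -> Tensor:
        """(B, N, 4) labeled points -> (B, feature_width) branch feature."""
        if isinstance(points, Tensor):
            points = points.data
        if points.ndim != 3 or points.shape[2] != 4:
            raise ValueError(
                f"anatomy encoder expects (B, N, 4) rows, got {points.shape}")
        labels = np.unique(points[:, :, 3])
        if not set(labels.astype(int)) <= {int(c) for c in CLASS_ORDER}:
            raise ValueError(f"unknown class labels {labels}")
        if len(set(labels.astype(int))) != N_CLASSES:
            raise ValueError("anatomy input must contain all 3 classes")
        emb = self._embed_input(points)
        b, n, cin = emb.shape
        # per-point MLPs run as one flat GEMM over all batch points
        h1 = self.stage1(Tensor(emb.reshape(b * n, cin)))
        w1 = h1.shape[1]
        g1 = h1.reshape(b, n, w1).max(axis=1)      # (B, w1) global feature
        g1b = (g1.reshape(b, 1, w1) + Tensor(np.zeros((1, n, 1), dtype=np.float32))
               ).reshape(b * n, w1)
        h2 = self.stage2(concat([h1, g1b], axis=1))
        g2 = h2.reshape(b, n, h2.shape[1]).max(axis=1)
        return self.fc(g2)


class AnatomyDecoder(Module):
    def __init__(self, config: AnatomyDecoderConfig, latent_dim: int,
                 rng: np.random.Generator):
        super().__init__()
        self.config = config
        self.latent_dim = latent_dim
        nc = config.n_coarse_per_class
        self.coarse_mlp = MLP(
            [latent_dim, *config.coarse_widths, N_CLASSES * nc * 3], rng)
        fold_in = 2 + 3 + latent_dim + N_CLASSES
        self.fold1 = MLP([fold_in, *config.fold_widths, 3], rng)
        self.fold2 = MLP([3 + 3 + latent_dim + N_CLASSES,
                          *config.fold_widths, 3], rng)
        g = config.grid_side
        lin = np.linspace(-config.grid_extent, config.grid_extent, g,
                          dtype=np.float32)
        uu, vv = np.meshgrid(lin, lin, indexing="ij")
        self.grid = np.column_stack([uu.ravel(), vv.ravel()])   # (g^2, 2)

    def forward(self, z: Tensor) -> AnatomyPrediction:
        cfg = self.config
        if z.shape[-1] != self.latent_dim:
            raise ValueError(
                f"latent dimension mismatch: got {z.shape[-1]}, expected {self.latent_dim}")
        b = z.shape[0]
        nc, g2 = cfg.n_coarse_per_class, cfg.grid_side ** 2
        coarse = self.coarse_mlp(z).reshape(b, N_CLASSES, nc, 3)

        # tile: every coarse point spawns g^2 folded points
        n_dense_total = N_CLASSES * nc * g2
        coarse_flat = coarse.reshape(b, N_CLASSES * nc, 1, 3)
        coarse_tiled = (coarse_flat + Tensor(
            np.zeros((1, 1, g2, 1), dtype=np.float32))
        ).reshape(b, n_dense_total, 3)

        grid_tiled = np.broadcast_to(
            self.grid[None, None, :, :], (b, N_CLASSES * nc, g2, 2)
        ).reshape(b, n_dense_total, 2).astype(np.float32)
        cls_ids = np.repeat(np.eye(N_CLASSES, dtype=np.float32),
                            nc * g2, axis=0)                     # (total, 3)
        cls_tiled = np.broadcast_to(cls_ids[None], (b, n_dense_total, N_CLASSES))
        z_tiled = (z.reshape(b, 1, self.latent_dim) + Tensor(
            np.zeros((1, n_dense_total, 1), dtype=np.float32)))

        flat = b * n_dense_total
        grid_flat = Tensor(np.ascontiguousarray(grid_tiled.reshape(flat, 2)))
        cls_flat = Tensor(np.ascontiguousarray(
            np.asarray(cls_tiled).reshape(flat, N_CLASSES)))
        coarse_flat2 = coarse_tiled.reshape(flat, 3)
        z_flat = z_tiled.reshape(flat, self.latent_dim)
        f1 = self.fold1(concat([grid_flat, coarse_flat2, z_flat, cls_flat], axis=1))
        f2 = self.fold2(concat([f1, coarse_flat2, z_flat, cls_flat], axis=1))
        dense = (coarse_flat2 + f2).reshape(b, N_CLASSES, nc * g2, 3)
        return AnatomyPrediction(coarse=coarse, dense=dense)


def prediction_to_cloud(pred: AnatomyPrediction, phase: Phase | str,
                        which: str = "dense", batch_index: int = 0,
                        unnormalize=None) -> AnatomyPointCloud:
    """Turn one batch element of a decoder output into an AnatomyPointCloud."""
    arr = (pred.dense if which == "dense" else pred.coarse).data[batch_index]
    pts = {}
    for i, cls in enumerate(CLASS_ORDER):
        block = np.asarray(arr[i], dtype=np.float64)
        pts[cls] = unnormalize(block) if unnormalize is not None else block
    return AnatomyPointCloud(pts, Phase(phase))
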
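"""The multi-domain VAE: three branches, one shared 12-dim latent space.

Encoder features from the ED anatomy branch, the ES anatomy branch and the
ECG branch are concatenated; a single shared pair of affine heads maps the
concatenation to the latent mean and log-variance.  A 12-dimensional vector
is sampled with the reparameterization trick and fed to all three decoders.
The two anatomy branches share an architecture but keep separate parameters.

Single-domain variants (bitemporal anatomy only, or ECG only) are the same
class with a restricted ``domains`` tuple; they serve as baselines for the
latent-space disease classification comparison.

Coordinates are normalized before encoding: per-record centroid removal
(over ED and ES jointly) and a fixed millimetre scale; the inverse transform
restores decoder outputs to mm.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .anatomy import (
    AnatomyDecoder, AnatomyDecoderConfig, AnatomyEncoder, AnatomyEncoderConfig,
    AnatomyPrediction, prediction_to_cloud,
)
from .ecg import ECGBranchConfig, ECGDecoder, ECGEncoder
from .nn import Linear, Module, Tensor, concat, no_grad
from .structures import (
    AnatomyPointCloud, CLASS_ORDER, ECGTrace, Normalization, Phase,
    SubjectRecord,
)

__all__ = ["LatentCode", "VAEConfig", "MultiDomainVAE"]

ALL_DOMAINS = ("ed", "es", "ecg")


@dataclasses.dataclass
class LatentCode:
    """Posterior mean/SD and one sampled realization for a batch of records."""

    mu: np.ndarray       # (B, D)
    sigma: np.ndarray    # (B, D), strictly positive
    z: np.ndarray | None = None

    def __post_init__(self):
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be strictly positive")


@dataclasses.dataclass
class VAEConfig:
    latent_dim: int = 12
    domains: tuple = ALL_DOMAINS
    anatomy_encoder: AnatomyEncoderConfig = dataclasses.field(
        default_factory=AnatomyEncoderConfig)
    anatomy_decoder: AnatomyDecoderConfig = dataclasses.field(
        default_factory=AnatomyDecoderConfig)
    ecg: ECGBranchConfig = dataclasses.field(default_factory=ECGBranchConfig)
    coord_scale: float = 60.0    # mm; coordinates are divided by this
    seed: int = 0

    def __post_init__(self):
        self.domains = tuple(self.domains)
        bad = set(self.domains) - set(ALL_DOMAINS)
        if bad or not self.domains:
            raise ValueError(f"domains must be a nonempty subset of {ALL_DOMAINS}")

    @staticmethod
    def small_preset(n_coarse: int = 16, grid_side: int = 2,
                     ecg_length: int = 100,
                     domains: tuple = ALL_DOMAINS, seed: int = 0) -> "VAEConfig":
        """Reduced-width configuration for CPU-scale experiments and tests."""
        return VAEConfig(
            latent_dim=12,
            domains=domains,
            anatomy_encoder=AnatomyEncoderConfig(
                stage1_widths=(24, 48), stage2_widths=(48, 96),
                fc_widths=(48, 48)),
            anatomy_decoder=AnatomyDecoderConfig(
                n_coarse_per_class=n_coarse, grid_side=grid_side,
                coarse_widths=(96, 96), fold_widths=(48, 48)),
            ecg=ECGBranchConfig(length=ecg_length, conv_channels=(8, 16),
                                fc_widths=(48, 32), decoder_dense_width=32),
            seed=seed,
        )


class MultiDomainVAE(Module):
    def __init__(self, config: VAEConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        feat = 0
        if "ed" in config.domains:
            self.enc_ed = AnatomyEncoder(config.anatomy_encoder, rng)
            self.dec_ed = AnatomyDecoder(config.anatomy_decoder,
                                         config.latent_dim, rng)
            feat += config.anatomy_encoder.feature_width
        if "es" in config.domains:
            self.enc_es = AnatomyEncoder(config.anatomy_encoder, rng)
            self.dec_es = AnatomyDecoder(config.anatomy_decoder,
                                         config.latent_dim, rng)
            feat += config.anatomy_encoder.feature_width
        if "ecg" in config.domains:
            self.enc_ecg = ECGEncoder(config.ecg, rng)
            self.dec_ecg = ECGDecoder(config.ecg, config.latent_dim, rng)
            feat += config.ecg.feature_width
        self.head_mu = Linear(feat, config.latent_dim, rng)
        self.head_logvar = Linear(feat, config.latent_dim, rng)

    # -- coordinate normalization --------------------------------------------
    def record_centroid(self, record: SubjectRecord) -> np.ndarray:
        pts = []
        if "ed" in self.config.domains:
            pts.append(np.vstack(list(record.ed.points_by_class.values())))
        if "es" in self.config.domains:
            pts.append(np.vstack(list(record.es.points_by_class.values())))
        if not pts:
            return np.zeros(3)
        return np.vstack(pts).mean(axis=0)

    def normalize_cloud(self, pc: AnatomyPointCloud,
                        centroid: np.ndarray) -> np.ndarray:
        """-> (N, 4) rows of (x, y, z, class) in normalized coordinates."""
        stacked = pc.stacked()
        stacked[:, :3] = (stacked[:, :3] - centroid) / self.config.coord_scale
        return stacked.astype(np.float32)

    def normalized_targets(self, pc: AnatomyPointCloud,
                           centroid: np.ndarray) -> list[np.ndarray]:
        return [((pc.points_by_class[cls] - centroid) / self.config.coord_scale
                 ).astype(np.float32) for cls in CLASS_ORDER]

    def unnormalize(self, arr: np.ndarray, centroid: np.ndarray) -> np.ndarray:
        return arr * self.config.coord_scale + centroid

    # -- batching -------------------------------------------------------------
    def prepare_record(self, record: SubjectRecord) -> dict:
        """Normalized arrays for one record (cacheable across training steps)."""
        self._check_complete(record)
        centroid = self.record_centroid(record)
        out: dict = {"centroid": centroid}
        if "ed" in self.config.domains:
            out["ed"] = self.normalize_cloud(record.ed, centroid)
            out["ed_targets"] = self.normalized_targets(record.ed, centroid)
        if "es" in self.config.domains:
            out["es"] = self.normalize_cloud(record.es, centroid)
            out["es_targets"] = self.normalized_targets(record.es, centroid)
        if "ecg" in self.config.domains:
            out["ecg"] = record.ecg.samples.astype(np.float32)
        return out

    def collate(self, prepared: list[dict]) -> dict:
        batch: dict = {"centroids": np.array([p["centroid"] for p in prepared])}
        for dom in ("ed", "es"):
            if dom in self.config.domains:
                batch[dom] = np.stack([p[dom] for p in prepared])
                batch[f"{dom}_targets"] = [p[f"{dom}_targets"] for p in prepared]
        if "ecg" in self.config.domains:
            batch["ecg"] = np.stack([p["ecg"] for p in prepared])
        return batch

    def prepare_batch(self, records: list[SubjectRecord]) -> dict:
        """Stack a list of records into dense arrays + per-class loss targets."""
        return self.collate([self.prepare_record(r) for r in records])

    def _check_complete(self, record: SubjectRecord) -> None:
        if "ed" in self.config.domains and record.ed is None:
            raise ValueError("record is missing the ED anatomy")
        if "es" in self.config.domains and record.es is None:
            raise ValueError("record is missing the ES anatomy")
        if "ecg" in self.config.domains and record.ecg is None:
            raise ValueError("record is missing the ECG")

    # -- model passes ----------------------------------------------------------
    def encode_batch(self, batch: dict) -> tuple[Tensor, Tensor]:
        """-> (mu, logvar) tensors of shape (B, latent_dim)."""
        feats = []
        if "ed" in self.config.domains:
            feats.append(self.enc_ed(batch["ed"]))
        if "es" in self.config.domains:
            feats.append(self.enc_es(batch["es"]))
        if "ecg" in self.config.domains:
            feats.append(self.enc_ecg(batch["ecg"]))
        h = feats[0] if len(feats) == 1 else concat(feats, axis=1)
        return self.head_mu(h), self.head_logvar(h)

    def encode_joint(self, records: list[SubjectRecord] | SubjectRecord,
                     sample_rng: np.random.Generator | None = None) -> LatentCode:
        """Posterior (mu, sigma) for records; optionally draws z."""
        if isinstance(records, SubjectRecord):
            records = [records]
        batch = self.prepare_batch(records)
        with no_grad():
            mu, logvar = self.encode_batch(batch)
        sigma = np.exp(0.5 * logvar.data.astype(np.float64))
        z = None
        if sample_rng is not None:
            z = mu.data + sigma * sample_rng.standard_normal(mu.shape)
        return LatentCode(mu=mu.data.astype(np.float64), sigma=sigma, z=z)

    @staticmethod
    def reparameterize(mu: Tensor, logvar: Tensor,
                       rng: np.random.Generator) -> Tensor:
        """z = mu + sigma * eps with eps ~ N(0, I) from the seeded stream."""
        eps = rng.standard_normal(mu.shape).astype(mu.data.dtype)
        return mu + (logvar * 0.5).exp() * Tensor(eps)

    def decode(self, z: Tensor | np.ndarray) -> dict:
        if not isinstance(z, Tensor):
            z = Tensor(np.atleast_2d(np.asarray(z, dtype=np.float32)))
        out: dict = {}
        if "ed" in self.config.domains:
            out["ed"] = self.dec_ed(z)
        if "es" in self.config.domains:
            out["es"] = self.dec_es(z)
        if "ecg" in self.config.domains:
            out["ecg"] = self.dec_ecg(z)
        return out

    # -- user-facing reconstruction/generation ---------------------------------
    def reconstruct(self, record: SubjectRecord) -> dict:
        """Eval-mode reconstruction through z = mu (no sampling); outputs in mm."""
        self.eval()
        batch = self.prepare_batch([record])
        with no_grad():
            mu, _ = self.encode_batch(batch)
            dec = self.decode(mu)
        centroid = batch["centroids"][0]
        return self._decode_to_domain(dec, centroid)

    def _decode_to_domain(self, dec: dict, centroid: np.ndarray,
                          batch_index: int = 0) -> dict:
        out: dict = {}
        unnorm = lambda arr: self.unnormalize(arr, centroid)
        if "ed" in dec:
            out["ed"] = prediction_to_cloud(dec["ed"], Phase.ED, "dense",
                                            batch_index, unnorm)
            out["ed_coarse"] = prediction_to_cloud(dec["ed"], Phase.ED, "coarse",
                                                   batch_index, unnorm)
        if "es" in dec:
            out["es"] = prediction_to_cloud(dec["es"], Phase.ES, "dense",
                                            batch_index, unnorm)
            out["es_coarse"] = prediction_to_cloud(dec["es"], Phase.ES, "coarse",
                                                   batch_index, unnorm)
        if "ecg" in dec:
            out["ecg"] = ECGTrace(dec["ecg"].data[batch_index].astype(np.float64),
                                  Normalization.RAW)
        return out

    def generate(self, z: np.ndarray) -> list[dict]:
        """Decode latent vectors (n, D) into mm-scale outputs (zero centroid)."""
        self.eval()
        z = np.atleast_2d(np.asarray(z, dtype=np.float32))
        with no_grad():
            dec = self.decode(Tensor(z))
        return [self._decode_to_domain(dec, np.zeros(3), i)
                for i in range(z.shape[0])]

    # -- checkpointing ---------------------------------------------------------
    def save(self, path: str | Path) -> None:
        cfg = dataclasses.asdict(self.config)
        arrays = {f"arr_{i}": a for i, a in enumerate(self.state_arrays())}
        np.savez_compressed(path, config=json.dumps(cfg), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "MultiDomainVAE":
        with np.load(path, allow_pickle=False) as data:
            cfg = json.loads(str(data["config"]))
            arrays = [data[f"arr_{i}"] for i in range(len(data.files) - 1)]
        config = VAEConfig(
            latent_dim=cfg["latent_dim"],
            domains=tuple(cfg["domains"]),
            anatomy_encoder=AnatomyEncoderConfig(
                **{k: tuple(v) if isinstance(v, list) else v
                   for k, v in cfg["anatomy_encoder"].items()}),
            anatomy_decoder=AnatomyDecoderConfig(
                **{k: tuple(v) if isinstance(v, list) else v
                   for k, v in cfg["anatomy_decoder"].items()}),
            ecg=ECGBranchConfig(
                **{k: tuple(v) if isinstance(v, list) else v
                   for k, v in cfg["ecg"].items()}),
            coord_scale=cfg["coord_scale"],
            seed=cfg["seed"],
        )
        model = cls(config)
        model.load_state_arrays(arrays)
        return model
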
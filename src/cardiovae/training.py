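"""Training loop: seeded mini-batch steps with Adam and annealed loss weights.

Every source of randomness (batch sampling, reparameterization noise) flows
from one ``numpy.random.Generator`` seeded by the train config, so a run is
bit-reproducible on the same machine.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .losses import (
    AnnealingSchedule, anatomy_loss, ecg_loss, kl_loss, schedule_weights,
    total_loss,
)
from .nn import Adam, Tensor, no_grad
from .structures import DatasetSplit, SubjectRecord
from .vae import MultiDomainVAE, VAEConfig

__all__ = ["TrainConfig", "TrainingDiverged", "train", "history_to_rows"]


@dataclasses.dataclass
class TrainConfig:
    batch_size: int = 4
    total_steps: int = 150_000
    learning_rate: float = 1e-4
    lr_final: float | None = None    # cosine-decay target; None = constant
    adam_betas: tuple = (0.9, 0.999)
    seed: int = 0
    val_every: int = 200
    squared_chamfer: bool = True     # training variant; reported metrics use mm

    def __post_init__(self):
        if self.batch_size < 1 or self.total_steps < 1:
            raise ValueError("batch size and total steps must be >= 1")


class TrainingDiverged(RuntimeError):
    """Raised when the loss becomes non-finite; carries diagnostic state."""

    def __init__(self, step: int, breakdown: dict):
        super().__init__(f"non-finite loss at step {step}: {breakdown}")
        self.step = step
        self.breakdown = breakdown


def _step_losses(model: MultiDomainVAE, batch: dict, weights, rng,
                 squared: bool, sample: bool = True):
    mu, logvar = model.encode_batch(batch)
    z = model.reparameterize(mu, logvar, rng) if sample else mu
    dec = model.decode(z)
    dom = model.config.domains
    # anatomy terms are expressed in physical units (mm^2, or mm when
    # unsquared) even though the branches operate on normalized coordinates:
    # the KL/ECG weighting of the schedule is calibrated against mm-scale
    # reconstruction losses
    unit = model.config.coord_scale ** (2 if squared else 1)
    l_ed = (anatomy_loss(dec["ed"], batch["ed_targets"], weights.alpha, squared)
            * unit if "ed" in dom else 0.0)
    l_es = (anatomy_loss(dec["es"], batch["es_targets"], weights.alpha, squared)
            * unit if "es" in dom else 0.0)
    l_ecg = ecg_loss(dec["ecg"], batch["ecg"]) if "ecg" in dom else 0.0
    l_kl = kl_loss(mu, logvar)
    return total_loss(l_ed, l_es, l_ecg, l_kl, weights)


def _evaluate_split(model: MultiDomainVAE, records: list[SubjectRecord],
                    weights, squared: bool, batch_size: int = 8) -> float:
    """Deterministic total loss over a split (z = mu, no sampling)."""
    model.eval()
    losses, counts = [], []
    with no_grad():
        for i in range(0, len(records), batch_size):
            chunk = records[i:i + batch_size]
            batch = model.prepare_batch(chunk)
            loss, _ = _step_losses(model, batch, weights, None, squared,
                                   sample=False)
            losses.append(float(loss.data))
            counts.append(len(chunk))
    model.train()
    return float(np.average(losses, weights=counts))


def train(model: MultiDomainVAE, dataset: DatasetSplit, config: TrainConfig,
          schedule: AnnealingSchedule | None = None) -> list[dict]:
    """Run the step loop; returns the loss history (one dict per step plus
    validation rows at the configured cadence)."""
    if not dataset.train:
        raise ValueError("empty training split")
    if schedule is None:
        schedule = AnnealingSchedule(total_steps=config.total_steps)
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters(), lr=config.learning_rate,
               betas=config.adam_betas)
    history: list[dict] = []
    model.train()
    n = len(dataset.train)
    prepared = [model.prepare_record(r) for r in dataset.train]
    for step in range(config.total_steps):
        if config.lr_final is not None:
            frac = step / max(config.total_steps - 1, 1)
            opt.lr = (config.lr_final + (config.learning_rate - config.lr_final)
                      * 0.5 * (1.0 + np.cos(np.pi * frac)))
        weights = schedule_weights(step, schedule)
        idx = rng.integers(0, n, size=config.batch_size)
        batch = model.collate([prepared[i] for i in idx])
        loss, breakdown = _step_losses(model, batch, weights, rng,
                                       config.squared_chamfer)
        if not np.isfinite(loss.data):
            raise TrainingDiverged(step, breakdown)
        opt.zero_grad()
        loss.backward()
        opt.step()
        row = {"step": step, "alpha": weights.alpha, "beta": weights.beta,
               "gamma": weights.gamma, **breakdown,
               "L_total": float(loss.data), "split": "train"}
        history.append(row)
        last = step == config.total_steps - 1
        if dataset.validation and (step % config.val_every == 0 or last):
            val = _evaluate_split(model, dataset.validation, weights,
                                  config.squared_chamfer)
            history.append({"step": step, "alpha": weights.alpha,
                            "beta": weights.beta, "gamma": weights.gamma,
                            "L_ED": np.nan, "L_ES": np.nan, "L_ECG": np.nan,
                            "L_KL": np.nan, "L_total": val, "split": "validation"})
    model.eval()
    return history


def history_to_rows(history: list[dict]):
    """History as a pandas DataFrame with the canonical column order."""
    import pandas as pd

    cols = ["step", "alpha", "beta", "gamma", "L_ED", "L_ES", "L_ECG",
            "L_KL", "L_total", "split"]
    return pd.DataFrame(history)[cols]
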
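"""Composite VAE loss: Chamfer anatomy terms, ECG MSE, KL, and the
monotonic annealing schedule for the three weights.

Total loss
    L_total = L_ED + L_ES + gamma * L_ECG + beta * L_KL
with each anatomy term a sum over the three substructure classes of
    CD(coarse_c, target_c) + alpha * CD(dense_c, target_c)
(classes unweighted).  Training starts with small alpha/beta and gamma so
the network first learns coarse global shape; alpha and gamma then ramp
linearly to 1, after which beta ramps to its 0.25 ceiling.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial.distance import cdist

from .nn import Tensor

__all__ = [
    "LossWeights", "AnnealingSchedule", "schedule_weights", "kl_divergence",
    "kl_loss", "ecg_loss", "chamfer_loss", "anatomy_loss", "total_loss",
]

_EPS = 1e-12


@dataclasses.dataclass
class LossWeights:
    alpha: float    # dense anatomy term
    beta: float     # KL term
    gamma: float    # ECG term

    def __post_init__(self):
        if min(self.alpha, self.beta, self.gamma) < 0:
            raise ValueError("loss weights must be nonnegative")


@dataclasses.dataclass
class AnnealingSchedule:
    """Piecewise-linear, nondecreasing weight ramps.

    alpha and gamma rise from their small initial values to 1 over their
    ramp windows; beta only starts rising after both have finished, capping
    at ``beta_max``.  Ramp milestones default to 0-40% of training for
    alpha/gamma and 50-90% for beta.
    """

    total_steps: int = 150_000
    alpha_init: float = 0.01
    beta_init: float = 0.01
    gamma_init: float = 0.1
    alpha_final: float = 1.0
    gamma_final: float = 1.0
    beta_max: float = 0.25
    alpha_ramp: tuple | None = None    # (start, end) steps
    gamma_ramp: tuple | None = None
    beta_ramp: tuple | None = None

    def __post_init__(self):
        t = self.total_steps
        if self.alpha_ramp is None:
            self.alpha_ramp = (0, int(0.4 * t))
        if self.gamma_ramp is None:
            self.gamma_ramp = (0, int(0.4 * t))
        if self.beta_ramp is None:
            self.beta_ramp = (int(0.5 * t), int(0.9 * t))
        for name in ("alpha_ramp", "gamma_ramp", "beta_ramp"):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi <= t):
                raise ValueError(f"{name} must satisfy 0 <= start <= end <= total")
        if self.beta_ramp[0] < max(self.alpha_ramp[1], self.gamma_ramp[1]):
            raise ValueError(
                "beta ramp must start only after alpha and gamma reach their "
                "final values")


def _ramp(step: int, lo: int, hi: int, v0: float, v1: float) -> float:
    if step <= lo:
        return v0
    if step >= hi or hi == lo:
        return v1
    return v0 + (v1 - v0) * (step - lo) / (hi - lo)


def schedule_weights(step: int, schedule: AnnealingSchedule) -> LossWeights:
    if not (0 <= step <= schedule.total_steps):
        raise ValueError(f"step {step} outside [0, {schedule.total_steps}]")
    return LossWeights(
        alpha=_ramp(step, *schedule.alpha_ramp, schedule.alpha_init,
                    schedule.alpha_final),
        beta=_ramp(step, *schedule.beta_ramp, schedule.beta_init,
                   schedule.beta_max),
        gamma=_ramp(step, *schedule.gamma_ramp, schedule.gamma_init,
                    schedule.gamma_final),
    )


def kl_divergence(mu: np.ndarray, sigma: np.ndarray) -> float:
    """Closed-form KL(N(mu, diag sigma^2) || N(0, I)).

    ``-1/2 sum_d (1 + log sigma_d^2 - mu_d^2 - sigma_d^2)``; always >= 0.
    """
    mu = np.asarray(mu, dtype=np.float64).reshape(-1)
    sigma = np.asarray(sigma, dtype=np.float64).reshape(-1)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be strictly positive")
    return float(-0.5 * np.sum(1.0 + 2.0 * np.log(sigma) - mu ** 2 - sigma ** 2))


def kl_loss(mu: Tensor, logvar: Tensor) -> Tensor:
    """Differentiable KL against the standard normal prior, averaged over batch."""
    term = 1.0 + logvar - mu * mu - logvar.exp()
    return term.sum(axis=1).mean() * -0.5


def ecg_loss(pred, target) -> Tensor | float:
    """Mean squared error between reconstructed and gold-standard signals."""
    if isinstance(pred, Tensor):
        t = np.asarray(target, dtype=pred.data.dtype)
        if pred.shape != t.shape:
            raise ValueError(f"ecg_loss shape mismatch {pred.shape} vs {t.shape}")
        d = pred - Tensor(t)
        return (d * d).mean()
    x = np.asarray(pred, dtype=np.float64).reshape(-1)
    y = np.asarray(target, dtype=np.float64).reshape(-1)
    if x.size != y.size:
        raise ValueError("ecg_loss length mismatch")
    return float(((x - y) ** 2).mean())


def chamfer_loss(pred: Tensor, target: np.ndarray, squared: bool = True) -> Tensor:
    """Differentiable Chamfer distance from a predicted (n, 3) tensor to a
    fixed target (m, 3) array; nearest neighbours are found outside the graph.
    """
    tgt = np.asarray(target, dtype=pred.data.dtype)
    if pred.data.size == 0 or tgt.size == 0:
        raise ValueError("Chamfer distance of an empty set is undefined")
    d = cdist(pred.data, tgt)
    idx1 = d.argmin(axis=1)               # nearest target per predicted point
    idx2 = d.argmin(axis=0)               # nearest predicted point per target

    diff1 = pred - Tensor(tgt[idx1])
    sq1 = (diff1 * diff1).sum(axis=1)
    diff2 = pred.take_rows(idx2) - Tensor(tgt)
    sq2 = (diff2 * diff2).sum(axis=1)
    if squared:
        return (sq1.mean() + sq2.mean()) * 0.5
    return ((sq1 + _EPS).sqrt().mean() + (sq2 + _EPS).sqrt().mean()) * 0.5


def anatomy_loss(pred, targets_by_class: list[np.ndarray], alpha: float,
                 squared: bool = True) -> Tensor:
    """Coarse + alpha * dense Chamfer summed over the three classes.

    ``pred`` is an AnatomyPrediction with tensors (B, 3, n, 3);
    ``targets_by_class`` holds per-batch-element lists of three (m, 3) arrays
    (or a single list of three arrays for B = 1).  Classes are unweighted.
    """
    coarse, dense = pred.coarse, pred.dense
    b = coarse.shape[0]
    if targets_by_class and isinstance(targets_by_class[0], np.ndarray):
        targets_by_class = [targets_by_class]
    if len(targets_by_class) != b:
        raise ValueError("anatomy_loss: batch size mismatch with targets")
    terms = []
    for bi in range(b):
        if len(targets_by_class[bi]) != 3:
            raise ValueError("anatomy_loss: need exactly 3 class targets")
        for ci in range(3):
            tgt = targets_by_class[bi][ci]
            terms.append(chamfer_loss(coarse[bi, ci], tgt, squared))
            terms.append(chamfer_loss(dense[bi, ci], tgt, squared) * alpha)
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return total * (1.0 / b)


def total_loss(l_ed: Tensor | float, l_es: Tensor | float,
               l_ecg: Tensor | float, l_kl: Tensor | float,
               weights: LossWeights):
    """Recombine per-branch terms; returns (scalar, breakdown dict)."""
    total = l_ed + l_es + l_ecg * weights.gamma + l_kl * weights.beta
    breakdown = {
        "L_ED": float(l_ed.data) if isinstance(l_ed, Tensor) else float(l_ed),
        "L_ES": float(l_es.data) if isinstance(l_es, Tensor) else float(l_es),
        "L_ECG": float(l_ecg.data) if isinstance(l_ecg, Tensor) else float(l_ecg),
        "L_KL": float(l_kl.data) if isinstance(l_kl, Tensor) else float(l_kl),
    }
    return total, breakdown
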
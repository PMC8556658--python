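"""Adversarial domain generalization: GRL, prediction heads and losses.

Every training subject is treated as a source domain.  A label head predicts
the sleep stage; a domain head, fed through a gradient reversal layer (GRL),
predicts the subject.  Both heads minimise cross-entropy, but the GRL flips
(and scales by ``beta``) the domain gradient on its way into the shared
feature extractor, so the features are driven toward subject-invariance
while staying discriminative for the staging task — the saddle-point
objective of domain-adversarial training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad


@dataclass
class DGHeads:
    """Affine label head, hidden-layer domain head and the reversal strength."""

    wy: np.ndarray  # [F, R_y]
    by: np.ndarray  # [R_y]
    wd_hidden: np.ndarray  # [F, H]
    bd_hidden: np.ndarray  # [H]
    wd: np.ndarray  # [H, R_d]
    bd: np.ndarray  # [R_d]
    beta: float = 0.5

    def __post_init__(self):
        if self.beta < 0:
            raise ValueError("beta must be nonnegative")

    @property
    def n_classes(self) -> int:
        return self.wy.shape[1]

    @property
    def n_domains(self) -> int:
        return self.wd.shape[1]

    @classmethod
    def init(
        cls,
        n_features: int,
        n_classes: int,
        n_domains: int,
        rng: np.random.Generator,
        hidden: int = 64,
        beta: float = 0.5,
    ) -> "DGHeads":
        if n_classes < 2:
            raise ValueError("R_y must be >= 2")
        glorot = lambda fan_in, fan_out: rng.normal(
            0.0, np.sqrt(2.0 / (fan_in + fan_out)), size=(fan_in, fan_out)
        )
        return cls(
            wy=glorot(n_features, n_classes),
            by=np.zeros(n_classes),
            wd_hidden=glorot(n_features, hidden),
            bd_hidden=np.zeros(hidden),
            wd=glorot(hidden, n_domains),
            bd=np.zeros(n_domains),
            beta=beta,
        )


def gradient_reversal(x: np.ndarray | ad.Tensor, beta: float):
    """Identity forward; backward gradient scaled by ``-beta``.

    On plain arrays this is simply the identity (there is no tape); inside
    the model it is the autodiff node that realises the adversarial sign.
    """
    if isinstance(x, ad.Tensor):
        return ad.grad_reverse(x, beta)
    if beta < 0:
        raise ValueError("beta must be nonnegative")
    return np.asarray(x, dtype=float).copy()


def label_logits_t(features: ad.Tensor, wy: ad.Tensor, by: ad.Tensor) -> ad.Tensor:
    return ad.add(ad.matmul(features, wy), by)


def domain_logits_t(
    features: ad.Tensor,
    wd_hidden: ad.Tensor,
    bd_hidden: ad.Tensor,
    wd: ad.Tensor,
    bd: ad.Tensor,
    beta: float,
) -> ad.Tensor:
    rev = ad.grad_reverse(features, beta)
    hidden = ad.relu(ad.add(ad.matmul(rev, wd_hidden), bd_hidden))
    return ad.add(ad.matmul(hidden, wd), bd)


def predict_heads(features: np.ndarray, heads: DGHeads) -> tuple[np.ndarray, np.ndarray]:
    """Softmax class and domain distributions for a feature vector or batch."""
    f = np.asarray(features, dtype=float)
    single = f.ndim == 1
    fb = f[None] if single else f
    if not np.all(np.isfinite(fb)):
        raise ValueError("features must be finite")
    y = ad.softmax(label_logits_t(ad.Tensor(fb), ad.Tensor(heads.wy), ad.Tensor(heads.by))).data
    d = ad.softmax(
        domain_logits_t(
            ad.Tensor(fb), ad.Tensor(heads.wd_hidden), ad.Tensor(heads.bd_hidden),
            ad.Tensor(heads.wd), ad.Tensor(heads.bd), heads.beta,
        )
    ).data
    return (y[0], d[0]) if single else (y, d)


def cross_entropy(pred: np.ndarray, true_index: np.ndarray | int, floor: float = 1e-12) -> float:
    """Batch-mean ``-log p[true]`` for simplex-valued predictions."""
    p = np.asarray(pred, dtype=float)
    single = p.ndim == 1
    pb = p[None] if single else p
    if not np.allclose(pb.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("predictions must sum to 1")
    idx = np.atleast_1d(np.asarray(true_index, dtype=int))
    picked = pb[np.arange(len(pb)), idx]
    if np.any(picked < floor):
        warnings.warn("zero predicted probability clamped before the log")
        picked = np.maximum(picked, floor)
    return float(-np.log(picked).mean())


def cross_entropy_t(
    logits: ad.Tensor, true_index: np.ndarray, label_smoothing: float = 0.0
) -> ad.Tensor:
    """Differentiable batch-mean cross-entropy from raw logits.

    With ``label_smoothing`` epsilon the target distribution is
    ``(1 - eps) * one_hot + eps / R``; the loss then has a positive floor and
    its gradient never vanishes, which keeps an adversarial head useful even
    once it classifies its task perfectly.
    """
    logp = ad.log_softmax(logits, axis=-1)
    idx = (np.arange(logits.shape[0]), np.asarray(true_index, dtype=int))
    if label_smoothing == 0.0:
        return ad.neg(ad.tmean(logp[idx]))
    eps = float(label_smoothing)
    r = logits.shape[-1]
    picked = ad.tmean(logp[idx])
    uniform = ad.tmean(ad.tsum(logp, axis=-1)) * (1.0 / r)
    return ad.neg(ad.add(ad.mul(picked, 1.0 - eps), ad.mul(uniform, eps)))


@dataclass
class LossReport:
    """Components of the training objective for one batch or epoch."""

    loss_y: float
    loss_d: float
    loss_graph: float
    gamma: float
    loss_total: float = field(init=False)

    def __post_init__(self):
        self.loss_total = total_loss(self.loss_y, self.loss_d, self.loss_graph, self.gamma)


def total_loss(loss_y: float, loss_d: float, loss_graph: float, gamma: float) -> float:
    """Combined objective ``L_y + L_d + gamma * L_graph``.

    The adversarial sign of the domain term is carried by the GRL, not by
    this sum: the domain head minimises ``L_d`` while the feature extractor
    receives ``-beta`` times its gradient, which realises the min-max
    objective without any explicit sign flip here.
    """
    for v in (loss_y, loss_d, loss_graph):
        if not np.isfinite(v):
            raise ValueError("loss components must be finite")
    return float(loss_y + loss_d + gamma * loss_graph)
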
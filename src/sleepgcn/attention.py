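"""Spatial and temporal attention over layer tensors ``[N, C, T]``.

Spatial attention scores how strongly each pair of channels should exchange
information at the current layer; temporal attention scores how much each
context epoch should contribute to each output timestep.  Both are bilinear
forms of the layer input squeezed through learnable projections, passed
through a logistic nonlinearity, remixed by an output gain matrix and
row-softmaxed, so each row of the resulting map is a probability
distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad


@dataclass
class SpatialAttentionParams:
    """Parameters of the N x N spatial attention map."""

    Vp: np.ndarray  # [N, N]
    bp: np.ndarray  # [N, N]
    Z1: np.ndarray  # [T]
    Z2: np.ndarray  # [C, T]
    Z3: np.ndarray  # [C]

    @classmethod
    def init(cls, n: int, c: int, t: int, rng: np.random.Generator, scale: float = 1e-2):
        u = lambda *shape: rng.uniform(-scale, scale, size=shape)
        return cls(Vp=u(n, n), bp=u(n, n), Z1=u(t), Z2=u(c, t), Z3=u(c))

    def validate(self, n: int, c: int, t: int) -> None:
        expected = {"Vp": (n, n), "bp": (n, n), "Z1": (t,), "Z2": (c, t), "Z3": (c,)}
        for name, shape in expected.items():
            actual = np.asarray(getattr(self, name)).shape
            if actual != shape:
                raise ValueError(f"spatial attention {name}: expected {shape}, got {actual}")


@dataclass
class TemporalAttentionParams:
    """Parameters of the T x T temporal attention map."""

    Vq: np.ndarray  # [T, T]
    bq: np.ndarray  # [T, T]
    M1: np.ndarray  # [N]
    M2: np.ndarray  # [C, N]
    M3: np.ndarray  # [C]

    @classmethod
    def init(cls, n: int, c: int, t: int, rng: np.random.Generator, scale: float = 1e-2):
        u = lambda *shape: rng.uniform(-scale, scale, size=shape)
        return cls(Vq=u(t, t), bq=u(t, t), M1=u(n), M2=u(c, n), M3=u(c))

    def validate(self, n: int, c: int, t: int) -> None:
        expected = {"Vq": (t, t), "bq": (t, t), "M1": (n,), "M2": (c, n), "M3": (c,)}
        for name, shape in expected.items():
            actual = np.asarray(getattr(self, name)).shape
            if actual != shape:
                raise ValueError(f"temporal attention {name}: expected {shape}, got {actual}")


def _as_batched(X: np.ndarray) -> tuple[np.ndarray, bool]:
    X = np.asarray(X, dtype=float)
    if X.ndim == 3:
        return X[None], False
    if X.ndim == 4:
        return X, True
    raise ValueError("layer tensor must be [N, C, T] or [B, N, C, T]")


def spatial_attention_t(
    X: ad.Tensor, Vp: ad.Tensor, bp: ad.Tensor, Z1: ad.Tensor, Z2: ad.Tensor, Z3: ad.Tensor
) -> ad.Tensor:
    """Differentiable spatial attention for batched input ``[B, N, C, T]``."""
    t1 = ad.einsum("bnct,t->bnc", X, Z1)
    t2 = ad.einsum("bnc,ct->bnt", t1, Z2)
    t3 = ad.einsum("c,bnct->bnt", Z3, X)
    scores = ad.add(ad.einsum("bmt,bnt->bmn", t2, t3), bp)
    P = ad.einsum("mn,bnk->bmk", Vp, ad.sigmoid(scores))
    return ad.softmax(P, axis=-1)


def temporal_attention_t(
    X: ad.Tensor, Vq: ad.Tensor, bq: ad.Tensor, M1: ad.Tensor, M2: ad.Tensor, M3: ad.Tensor
) -> ad.Tensor:
    """Differentiable temporal attention for batched input ``[B, N, C, T]``."""
    u1 = ad.einsum("bnct,n->btc", X, M1)
    u2 = ad.einsum("btc,cn->btn", u1, M2)
    u3 = ad.einsum("c,bnct->bnt", M3, X)
    scores = ad.add(ad.einsum("bun,bnv->buv", u2, u3), bq)
    Q = ad.einsum("uv,bvt->but", Vq, ad.sigmoid(scores))
    return ad.softmax(Q, axis=-1)


def apply_temporal_attention_t(X: ad.Tensor, Q_prime: ad.Tensor) -> ad.Tensor:
    """Mix the temporal axis: ``X_hat[..., t] = sum_u X[..., u] Q'[u, t]``."""
    return ad.einsum("bncu,but->bnct", X, Q_prime)


def spatial_attention(X: np.ndarray, p: SpatialAttentionParams) -> np.ndarray:
    """Row-stochastic N x N spatial attention map for ``[N, C, T]`` input."""
    Xb, batched = _as_batched(X)
    _, n, c, t = Xb.shape
    p.validate(n, c, t)
    out = spatial_attention_t(
        ad.Tensor(Xb), ad.Tensor(p.Vp), ad.Tensor(p.bp),
        ad.Tensor(p.Z1), ad.Tensor(p.Z2), ad.Tensor(p.Z3),
    ).data
    return out if batched else out[0]


def temporal_attention(X: np.ndarray, q: TemporalAttentionParams) -> np.ndarray:
    """Row-stochastic T x T temporal attention map for ``[N, C, T]`` input."""
    Xb, batched = _as_batched(X)
    _, n, c, t = Xb.shape
    q.validate(n, c, t)
    out = temporal_attention_t(
        ad.Tensor(Xb), ad.Tensor(q.Vq), ad.Tensor(q.bq),
        ad.Tensor(q.M1), ad.Tensor(q.M2), ad.Tensor(q.M3),
    ).data
    return out if batched else out[0]


def apply_temporal_attention(X: np.ndarray, Q_prime: np.ndarray) -> np.ndarray:
    """Temporal mixing of a layer tensor by an attention map."""
    import warnings

    Xb, batched = _as_batched(X)
    Q = np.asarray(Q_prime, dtype=float)
    if Q.ndim == 2:
        Qb = np.broadcast_to(Q, (Xb.shape[0],) + Q.shape)
    else:
        Qb = Q
    if not np.allclose(Qb.sum(axis=-1), 1.0, atol=1e-6):
        warnings.warn("temporal attention map is not row-stochastic")
    out = apply_temporal_attention_t(ad.Tensor(Xb), ad.Tensor(Qb)).data
    return out if batched else out[0]
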
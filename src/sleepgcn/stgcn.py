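"""Spatial-temporal graph convolution blocks.

The spatial step is a Chebyshev spectral graph convolution of order ``K-1``:
the filter is a polynomial ``sum_k theta_k T_k(L_tilde)`` in the scaled
Laplacian, so information from 0..K-1-hop neighbourhoods is aggregated.  The
attention map modulates each polynomial term elementwise, letting the model
re-weight individual edges per window.  The temporal step is a standard
same-padded convolution along the context axis, capturing stage-transition
structure; both steps use ReLU activations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad


@dataclass
class ChebFilter:
    """Chebyshev filter bank ``Theta [K, C_in, C_out]``."""

    Theta: np.ndarray
    K: int

    def __post_init__(self):
        self.Theta = np.asarray(self.Theta, dtype=float)
        if self.K < 1:
            raise ValueError("Chebyshev order K must be >= 1")
        if self.Theta.shape[0] != self.K:
            raise ValueError("Theta leading dimension must equal K")


@dataclass
class TemporalConvParams:
    """Temporal convolution kernel ``Phi [C_out, C_in, k_t]`` plus bias."""

    Phi: np.ndarray
    bias: np.ndarray | None = None

    def __post_init__(self):
        self.Phi = np.asarray(self.Phi, dtype=float)
        if self.Phi.ndim != 3:
            raise ValueError("Phi must be [C_out, C_in, k_t]")
        if self.Phi.shape[2] % 2 != 1:
            raise ValueError("temporal kernel length k_t must be odd")
        if self.bias is None:
            self.bias = np.zeros(self.Phi.shape[0])
        self.bias = np.asarray(self.bias, dtype=float)


def cheb_polynomials(L_tilde: np.ndarray, K: int) -> list[np.ndarray]:
    """Chebyshev polynomial basis ``[T_0, ..., T_{K-1}]`` of the scaled Laplacian.

    ``T_0 = I``, ``T_1 = L_tilde``, ``T_k = 2 L_tilde T_{k-1} - T_{k-2}``.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    L = np.asarray(L_tilde, dtype=float)
    if L.ndim != 2 or L.shape[0] != L.shape[1]:
        raise ValueError("L_tilde must be square")
    radius = float(np.abs(np.linalg.eigvals(L)).max())
    if radius > 1 + 1e-6:
        raise ValueError(f"scaled Laplacian spectral radius {radius:.4f} exceeds 1")
    polys = [np.eye(L.shape[0])]
    if K >= 2:
        polys.append(L.copy())
    for _ in range(2, K):
        polys.append(2.0 * L @ polys[-1] - polys[-2])
    return polys


def cheb_polynomials_t(L_tilde: ad.Tensor, K: int) -> list[ad.Tensor]:
    """Differentiable Chebyshev basis for batched ``[B, N, N]`` Laplacians."""
    n = L_tilde.shape[-1]
    eye = np.broadcast_to(np.eye(n), L_tilde.shape).copy()
    polys = [ad.Tensor(eye)]
    if K >= 2:
        polys.append(L_tilde)
    for _ in range(2, K):
        polys.append(ad.sub(ad.mul(ad.matmul(L_tilde, polys[-1]), 2.0), polys[-2]))
    return polys


def cheb_graph_conv_t(
    X_hat: ad.Tensor, cheb: list[ad.Tensor], Theta: ad.Tensor, P_prime: ad.Tensor,
    activation=ad.relu,
) -> ad.Tensor:
    """Attention-modulated Chebyshev convolution on ``[B, N, C_in, T]`` input.

    Per timestep: ``out = ReLU( sum_k (T_k(L) ⊙ P') X Theta_k )`` where ``⊙``
    is the elementwise product that lets the spatial attention map re-weight
    the edges used by every polynomial term.
    """
    K = len(cheb)
    terms = None
    for k in range(K):
        Ak = ad.mul(cheb[k], P_prime)  # broadcast if cheb[k] is [N, N]
        theta_k = Theta[k]  # [C_in, C_out]
        spec = "bmn,bnct,co->bmot" if Ak.ndim == 3 else "mn,bnct,co->bmot"
        term = ad.einsum(spec, Ak, X_hat, theta_k)
        terms = term if terms is None else ad.add(terms, term)
    return activation(terms)


def cheb_graph_conv(
    X_hat: np.ndarray,
    cheb: list[np.ndarray],
    Theta: np.ndarray,
    P_prime: np.ndarray,
) -> np.ndarray:
    """Numpy front-end of :func:`cheb_graph_conv_t` for ``[N, C, T]`` input."""
    X = np.asarray(X_hat, dtype=float)
    batched = X.ndim == 4
    Xb = X if batched else X[None]
    Theta = np.asarray(Theta, dtype=float)
    if Theta.shape[0] != len(cheb):
        raise ValueError("Theta leading dimension must equal the number of polynomials")
    if Theta.shape[1] != Xb.shape[2]:
        raise ValueError(
            f"channel mismatch: input has {Xb.shape[2]} channels, Theta expects {Theta.shape[1]}"
        )
    P = np.asarray(P_prime, dtype=float)
    Pb = P if P.ndim == 3 else np.broadcast_to(P, (Xb.shape[0],) + P.shape)
    out = cheb_graph_conv_t(
        ad.Tensor(Xb), [ad.Tensor(np.asarray(c, dtype=float)) for c in cheb],
        ad.Tensor(Theta), ad.Tensor(Pb),
    ).data
    return out if batched else out[0]


def temporal_conv_t(X: ad.Tensor, Phi: ad.Tensor, bias: ad.Tensor, activation=ad.relu) -> ad.Tensor:
    """Same-padded temporal convolution + ReLU on ``[B, N, C_in, T]`` input."""
    k_t = Phi.shape[2]
    half = k_t // 2
    T = X.shape[-1]
    Xp = ad.pad_last(X, half, half)
    out = None
    for tau in range(k_t):
        sl = Xp[..., tau : tau + T]
        term = ad.einsum("oc,bnct->bnot", Phi[:, :, tau], sl)
        out = term if out is None else ad.add(out, term)
    out = ad.add(out, ad.reshape(bias, (1, 1, -1, 1)))
    return activation(out)


def temporal_conv(X: np.ndarray, params: TemporalConvParams) -> np.ndarray:
    """Numpy front-end of the temporal convolution for ``[N, C, T]`` input."""
    Xa = np.asarray(X, dtype=float)
    batched = Xa.ndim == 4
    Xb = Xa if batched else Xa[None]
    if params.Phi.shape[2] > Xb.shape[-1]:
        raise ValueError("temporal kernel longer than the sequence")
    if params.Phi.shape[1] != Xb.shape[2]:
        raise ValueError("channel mismatch between input and kernel")
    out = temporal_conv_t(ad.Tensor(Xb), ad.Tensor(params.Phi), ad.Tensor(params.bias)).data
    return out if batched else out[0]


def fuse_views(X_fc: np.ndarray | ad.Tensor, X_dc: np.ndarray | ad.Tensor):
    """Concatenate the two branch outputs along the channel axis."""
    if isinstance(X_fc, ad.Tensor) or isinstance(X_dc, ad.Tensor):
        a, b = ad.astensor(X_fc), ad.astensor(X_dc)
        if a.shape[:-2] != b.shape[:-2] or a.shape[-1] != b.shape[-1]:
            raise ValueError("branch outputs must share node and temporal dimensions")
        return ad.concatenate([a, b], axis=-2)
    a, b = np.asarray(X_fc, dtype=float), np.asarray(X_dc, dtype=float)
    if a.shape[:-2] != b.shape[:-2] or a.shape[-1] != b.shape[-1]:
        raise ValueError("branch outputs must share node and temporal dimensions")
    return np.concatenate([a, b], axis=-2)
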
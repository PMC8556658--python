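"""Brain-graph construction: learned functional connectivity and distance view.

Two complementary views of the same montage are used.  The functional
connectivity (FC) view is *learned*: edge weights are a row-softmax of
``ReLU(w^T |x_m - x_n|)`` over node-feature differences, with a loss that
pulls strongly connected pairs toward similar features while an L2 penalty
keeps the graph sparse.  The distance (DC) view is fixed a priori from the
physical electrode geometry: a Gaussian kernel of Euclidean distance, so
nearby electrodes couple strongly.  Spectral filtering uses the scaled
Laplacian, whose spectrum lies in [-1, 1].
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

from . import autodiff as ad
from .features import ChannelMontage, FeatureMatrix

logger = logging.getLogger(__name__)


@dataclass
class GraphLearner:
    """Learnable weight vector of the adaptive FC graph (one weight per feature)."""

    w: np.ndarray
    lambda_reg: float = 0.001

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=float).ravel()
        if not np.all(np.isfinite(self.w)):
            raise ValueError("graph learner weights must be finite")
        if self.lambda_reg <= 0:
            raise ValueError("lambda_reg must be positive")


@dataclass
class AdjacencySet:
    """Both adjacency views plus their scaled Laplacians."""

    A_fc: np.ndarray
    A_dc: np.ndarray
    L_tilde_fc: np.ndarray = field(default=None)
    L_tilde_dc: np.ndarray = field(default=None)


# ---------------------------------------------------------------------------
# learned functional connectivity
# ---------------------------------------------------------------------------

def fc_adjacency_t(x_center: ad.Tensor, w: ad.Tensor) -> ad.Tensor:
    """Differentiable FC adjacency for a batch of feature matrices ``[B, N, Fd]``."""
    b, n, f = x_center.shape
    x1 = ad.reshape(x_center, (b, n, 1, f))
    x2 = ad.reshape(x_center, (b, 1, n, f))
    diff = ad.absolute(ad.sub(x1, x2))  # [B, N, N, Fd]
    logits = ad.relu(ad.einsum("bmnf,f->bmn", diff, w))
    return ad.softmax(logits, axis=-1)


def learn_fc_adjacency(X: FeatureMatrix | np.ndarray, learner: GraphLearner) -> np.ndarray:
    """Adaptive functional-connectivity adjacency (row-stochastic, entries in (0, 1])."""
    values = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("feature matrix contains non-finite entries")
    n, fd = values.shape
    if learner.w.shape != (fd,):
        raise ValueError(f"learner weight length {learner.w.shape[0]} != Fd {fd}")
    out = fc_adjacency_t(ad.Tensor(values[None]), ad.Tensor(learner.w))
    return out.data[0]


def graph_loss_t(x_center: ad.Tensor, A_fc: ad.Tensor, lambda_reg: float) -> ad.Tensor:
    """Differentiable graph-learning loss, averaged over the batch."""
    b, n, f = x_center.shape
    x1 = ad.reshape(x_center, (b, n, 1, f))
    x2 = ad.reshape(x_center, (b, 1, n, f))
    diff = ad.sub(x1, x2)
    sq = ad.einsum("bmnf,bmnf->bmn", diff, diff)
    smooth = ad.tsum(ad.mul(sq, A_fc))
    frob = ad.tsum(ad.square(A_fc))
    total = ad.add(smooth, ad.mul(frob, float(lambda_reg)))
    return ad.mul(total, 1.0 / b)


def graph_learning_loss(
    X: FeatureMatrix | np.ndarray, A_fc: np.ndarray, lambda_reg: float = 0.001
) -> float:
    """Smoothness + sparsity objective of the learned graph.

    ``sum_{m,n} ||x_m - x_n||^2 A[m,n] + lambda * ||A||_F^2``
    """
    if lambda_reg < 0:
        raise ValueError("lambda_reg must be nonnegative")
    values = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    A_fc = np.asarray(A_fc, dtype=float)
    rows = A_fc.sum(axis=1)
    if not np.allclose(rows, 1.0, atol=1e-6):
        raise ValueError("A_fc must be row-stochastic")
    diff = values[:, None, :] - values[None, :, :]
    sq = (diff**2).sum(axis=2)
    return float((sq * A_fc).sum() + lambda_reg * (A_fc**2).sum())


# ---------------------------------------------------------------------------
# distance view
# ---------------------------------------------------------------------------

def build_distance_adjacency(
    montage: ChannelMontage,
    sigma: float | None = None,
    threshold: float = 0.1,
) -> np.ndarray:
    """Gaussian kernel of pairwise electrode distance, thresholded and hollow.

    ``A[m, n] = exp(-||c_m - c_n||^2 / (2 sigma^2))`` for ``m != n``; entries
    below ``threshold`` are cut to zero.  ``sigma`` defaults to the mean
    pairwise distance, which keeps weights in a usable range for any montage
    scale.
    """
    if montage.n_channels < 2:
        raise ValueError("montage must contain at least 2 channels")
    if not (0 <= threshold < 1):
        raise ValueError("threshold must lie in [0, 1)")
    coords = montage.coords
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    off = dist[~np.eye(len(coords), dtype=bool)]
    if np.any(off == 0):
        warnings.warn("duplicate electrode coordinates: their edge weight is 1")
    if sigma is None:
        sigma = float(off.mean())
        if sigma == 0:
            sigma = 1.0
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    A = np.exp(-(dist**2) / (2.0 * sigma**2))
    np.fill_diagonal(A, 0.0)
    A[A < threshold] = 0.0
    if not A.any():
        warnings.warn("distance adjacency is all zero: graph is disconnected")
    return A


# ---------------------------------------------------------------------------
# Laplacians
# ---------------------------------------------------------------------------

def scaled_laplacian(A: np.ndarray) -> np.ndarray:
    """``(2 / lambda_max) (D - A) - I`` with spectrum in [-1, 1].

    Asymmetric input (e.g. the row-softmaxed FC adjacency) is symmetrised as
    ``(A + A^T) / 2`` first, because the spectral filter assumes a symmetric
    Laplacian.  An all-zero graph falls back to ``lambda_max = 2`` and returns
    ``-I``.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if np.any(A < 0):
        raise ValueError("adjacency must be nonnegative")
    if not np.allclose(A, A.T):
        A = 0.5 * (A + A.T)
    n = A.shape[0]
    L = np.diag(A.sum(axis=1)) - A
    lam_max = float(np.linalg.eigvalsh(L).max())
    if lam_max <= 0:
        warnings.warn("zero graph: using lambda_max = 2 fallback (L_tilde = -I)")
        lam_max = 2.0
    return (2.0 / lam_max) * L - np.eye(n)


def laplacian_minus_identity_t(A_sym: ad.Tensor) -> ad.Tensor:
    """Differentiable ``L - I`` for batched symmetric adjacency ``[B, N, N]``.

    Inside the model the maximum Laplacian eigenvalue of the learned graph is
    approximated by 2 (exact for bipartite regular graphs, standard for
    Chebyshev nets), which avoids differentiating an eigendecomposition.
    """
    n = A_sym.shape[-1]
    eye = np.eye(n)
    rowsum = ad.tsum(A_sym, axis=-1)
    D = ad.einsum("bm,mn->bmn", rowsum, eye)
    L = ad.sub(D, A_sym)
    return ad.sub(L, ad.Tensor(eye))


# ---------------------------------------------------------------------------
# fixed functional-connectivity baselines
# ---------------------------------------------------------------------------

def _pcc_matrix(data: np.ndarray) -> np.ndarray:
    data = np.asarray(data, dtype=float)
    std = data.std(axis=1)
    constant = std == 0
    if constant.any():
        warnings.warn("constant channel(s): their correlations are defined as 0")
    safe = data.copy()
    safe[constant] += np.arange(data.shape[1])  # placeholder, rows zeroed below
    C = np.abs(np.corrcoef(safe))
    C[constant, :] = 0.0
    C[:, constant] = 0.0
    C[np.diag_indices_from(C)] = np.where(constant, 0.0, 1.0)
    return C


def _plv_matrix(data: np.ndarray) -> np.ndarray:
    phases = np.angle(hilbert(np.asarray(data, dtype=float), axis=1))
    z = np.exp(1j * phases)
    n = data.shape[0]
    P = np.empty((n, n))
    for m in range(n):
        P[m] = np.abs((z[m][None, :] * np.conj(z)).mean(axis=1))
    return P


def _mi_matrix(data: np.ndarray, bins: int | None = None) -> np.ndarray:
    data = np.asarray(data, dtype=float)
    n, ts = data.shape
    if bins is None:
        bins = int(np.ceil(np.sqrt(ts)))
    M = np.zeros((n, n))
    for m in range(n):
        for k in range(m, n):
            joint, _, _ = np.histogram2d(data[m], data[k], bins=bins)
            p = joint / joint.sum()
            pm = p.sum(axis=1, keepdims=True)
            pk = p.sum(axis=0, keepdims=True)
            mask = p > 0
            mi = (p[mask] * np.log(p[mask] / (pm @ pk)[mask])).sum()
            M[m, k] = M[k, m] = mi
    lo, hi = M.min(), M.max()
    if hi > lo:
        M = (M - lo) / (hi - lo)
    return M


def fixed_adjacency(
    method: str,
    data: np.ndarray | None = None,
    n_channels: int | None = None,
    k: int | None = None,
    bins: int | None = None,
) -> np.ndarray:
    """Fixed-connectivity baselines: ``full``, ``knn``, ``pcc``, ``plv``, ``mi``.

    ``data`` is a per-channel time-series matrix ``[N, Ts]`` (required for all
    methods except ``full`` when ``n_channels`` is given).  ``knn`` keeps each
    channel's ``k`` most correlated neighbours and is symmetrised by
    ``max(A, A^T)``.
    """
    method = method.lower()
    if method == "full":
        n = n_channels if n_channels is not None else np.asarray(data).shape[0]
        return np.ones((n, n))
    if data is None:
        raise ValueError(f"method {method!r} requires per-channel time series")
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    if method == "pcc":
        return _pcc_matrix(data)
    if method == "plv":
        return _plv_matrix(data)
    if method == "mi":
        return _mi_matrix(data, bins=bins)
    if method == "knn":
        if k is None or not (0 < k < n):
            raise ValueError("knn requires 0 < k < N")
        sim = _pcc_matrix(data)
        np.fill_diagonal(sim, -np.inf)
        A = np.zeros((n, n))
        for m in range(n):
            A[m, np.argsort(sim[m])[-k:]] = 1.0
        return np.maximum(A, A.T)
    raise ValueError(f"unknown fixed-adjacency method {method!r}")


def export_adjacency(path, A: np.ndarray, channel_names: list[str]) -> None:
    """Write an adjacency matrix as a tab-delimited table with name headers."""
    A = np.asarray(A, dtype=float)
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(channel_names) + "\n")
        for name, row in zip(channel_names, A):
            fh.write(name + "\t" + "\t".join(f"{v:.8g}" for v in row) + "\n")


def read_adjacency(path) -> tuple[np.ndarray, list[str]]:
    """Read a matrix written by :func:`export_adjacency`."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
        rows = [line.rstrip("\n").split("\t")[1:] for line in fh if line.strip()]
    return np.array(rows, dtype=float), header
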
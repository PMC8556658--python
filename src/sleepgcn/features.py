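"""Epoched recordings, differential-entropy features and context windows.

A polysomnography recording is segmented into 30-second epochs, each labelled
with one of the five AASM stages (Wake, N1, N2, N3, REM).  Every epoch is
summarised per channel by differential entropy (DE) in a set of frequency
bands; consecutive epochs around a centre epoch form the temporal context
window the classifier consumes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

logger = logging.getLogger(__name__)

STAGE_NAMES = ("Wake", "N1", "N2", "N3", "REM")

#: canonical EEG bands (Hz); six bands so Fd defaults to 6 per signal
DEFAULT_BANDS: tuple[tuple[float, float], ...] = (
    (0.5, 4.0),   # delta
    (4.0, 8.0),   # theta
    (8.0, 13.0),  # alpha
    (13.0, 16.0),  # sigma
    (16.0, 30.0),  # beta
    (30.0, 45.0),  # gamma
)

DEFAULT_BAND_NAMES = ("delta", "theta", "alpha", "sigma", "beta", "gamma")


@dataclass
class ChannelMontage:
    """Electrode names (10-20 convention) and unit-sphere 3-D coordinates."""

    names: list[str]
    coords: np.ndarray  # [N, 3]

    def __post_init__(self):
        self.names = list(self.names)
        self.coords = np.asarray(self.coords, dtype=float)
        if len(set(self.names)) != len(self.names):
            raise ValueError("montage channel names must be unique")
        if self.coords.shape != (len(self.names), 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match {len(self.names)} channels"
            )
        norms = np.linalg.norm(self.coords, axis=1)
        if np.any(np.abs(norms - 1.0) > 0.1):
            raise ValueError("montage coordinates must lie within 10% of the unit sphere")

    @property
    def n_channels(self) -> int:
        return len(self.names)


@dataclass
class EpochedRecording:
    """Raw per-subject signal tensor ``[N, Ts, L]`` with stage labels."""

    signal: np.ndarray
    sampling_rate: float
    labels: np.ndarray
    subject_id: str
    montage: ChannelMontage

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.signal.ndim != 3:
            raise ValueError("signal must be [channels, samples, epochs]")
        n, ts, L = self.signal.shape
        if n < 2:
            raise ValueError("need at least 2 channels")
        if n != self.montage.n_channels:
            raise ValueError("signal channel count does not match montage")
        if ts != int(round(30 * self.sampling_rate)):
            raise ValueError(
                f"epoch length {ts} does not equal 30 s at {self.sampling_rate} Hz"
            )
        if self.labels.shape != (L,):
            raise ValueError("labels length must equal the number of epochs")

    @property
    def n_epochs(self) -> int:
        return self.signal.shape[2]


@dataclass
class FeatureMatrix:
    """Per-epoch node features ``[N, Fd]`` (one row per channel)."""

    values: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] < 1:
            raise ValueError("feature matrix must be [channels, features] with Fd >= 1")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite entries")
        if not self.feature_names:
            self.feature_names = [f"f{j}" for j in range(self.values.shape[1])]


@dataclass
class ContextWindow:
    """``2d+1`` consecutive epochs of features centred on the epoch to classify."""

    features: np.ndarray  # [N, Fd, Tn], oldest -> newest
    label: int
    subject_id: str
    center_index: int

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 3:
            raise ValueError("window features must be [channels, features, time]")
        if self.features.shape[2] % 2 != 1:
            raise ValueError("window length Tn must be odd (Tn = 2d + 1)")


def extract_de_features(
    rec: EpochedRecording,
    bands: tuple[tuple[float, float], ...] = DEFAULT_BANDS,
    band_names: tuple[str, ...] | None = None,
    filter_order: int = 4,
    var_floor: float = 1e-12,
) -> list[FeatureMatrix]:
    """Differential entropy per channel and frequency band, one matrix per epoch.

    Each band is isolated with a zero-phase Butterworth band-pass of the given
    order; the DE of a (near-)Gaussian band-limited signal is
    ``0.5 * ln(2 * pi * e * var)``.  Variances below ``var_floor`` are floored
    so silent channels yield a finite feature.
    """
    nyquist = rec.sampling_rate / 2.0
    for low, high in bands:
        if not (0 < low < high <= nyquist):
            raise ValueError(f"band ({low}, {high}) Hz invalid for Nyquist {nyquist} Hz")
    if band_names is None:
        band_names = (
            list(DEFAULT_BAND_NAMES[: len(bands)])
            if bands == DEFAULT_BANDS
            else [f"{lo:g}-{hi:g}Hz" for lo, hi in bands]
        )
    n, _, L = rec.signal.shape
    de = np.empty((L, n, len(bands)))
    for b, (low, high) in enumerate(bands):
        sos = sps.butter(filter_order, [low, high], btype="bandpass", fs=rec.sampling_rate, output="sos")
        filtered = sps.sosfiltfilt(sos, rec.signal, axis=1)
        var = filtered.var(axis=1)  # [N, L]
        var = np.maximum(var, var_floor)
        de[:, :, b] = (0.5 * np.log(2.0 * np.pi * np.e * var)).T
    names = list(band_names)
    return [FeatureMatrix(de[i], names) for i in range(L)]


def differential_entropy(var: np.ndarray | float) -> np.ndarray | float:
    """Closed-form DE of a Gaussian with the given variance."""
    return 0.5 * np.log(2.0 * np.pi * np.e * np.asarray(var, dtype=float))


def build_context_windows(
    feature_list: list[FeatureMatrix],
    labels: np.ndarray,
    subject_id: str,
    d: int,
) -> list[ContextWindow]:
    """Assemble temporal context windows of ``Tn = 2d + 1`` epochs.

    The first and last ``d`` epochs lack full context and are dropped, so
    exactly ``L - 2d`` windows are produced; window ``i`` is centred on epoch
    ``i + d`` and carries that epoch's stage label.
    """
    if d < 0:
        raise ValueError("context radius d must be >= 0")
    L = len(feature_list)
    if L <= 2 * d:
        raise ValueError(f"need more than 2d epochs to form any window (L={L}, d={d})")
    labels = np.asarray(labels, dtype=int)
    if labels.shape != (L,):
        raise ValueError("labels length must match feature list")
    stacked = np.stack([fm.values for fm in feature_list], axis=2)  # [N, Fd, L]
    windows = []
    for center in range(d, L - d):
        windows.append(
            ContextWindow(
                features=stacked[:, :, center - d : center + d + 1].copy(),
                label=int(labels[center]),
                subject_id=subject_id,
                center_index=center,
            )
        )
    return windows


class Standardizer:
    """Per-(channel, feature) affine standardisation fit on training windows only.

    Statistics are pooled over training windows and their temporal axis;
    applying the same affine map to held-out windows avoids test-set leakage.
    Constant features are left untouched (and logged) rather than divided by
    zero.
    """

    def __init__(self):
        self.mean_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None

    def fit(self, windows: list[ContextWindow]) -> "Standardizer":
        if not windows:
            raise ValueError("cannot fit a standardizer on zero windows")
        data = np.concatenate([w.features for w in windows], axis=2)  # [N, Fd, total_T]
        self.mean_ = data.mean(axis=2)
        std = data.std(axis=2)
        # relative floor: summation round-off on a constant column leaves a
        # tiny nonzero std, which must still count as degenerate
        degenerate = std <= 1e-12 * np.maximum(1.0, np.abs(self.mean_))
        if degenerate.any():
            idx = np.argwhere(degenerate)
            logger.warning(
                "standardizer: %d constant (channel, feature) cells left unscaled: %s",
                len(idx),
                idx[:5].tolist(),
            )
            warnings.warn("constant feature columns left uncentered and unscaled")
            self.mean_ = np.where(degenerate, 0.0, self.mean_)
            std = np.where(degenerate, 1.0, std)
        self.scale_ = std
        return self

    def transform(self, windows: list[ContextWindow]) -> list[ContextWindow]:
        if self.mean_ is None:
            raise RuntimeError("standardizer has not been fit")
        out = []
        for w in windows:
            feats = (w.features - self.mean_[:, :, None]) / self.scale_[:, :, None]
            out.append(ContextWindow(feats, w.label, w.subject_id, w.center_index))
        return out

    def fit_transform(self, windows: list[ContextWindow]) -> list[ContextWindow]:
        return self.fit(windows).transform(windows)


def standardize_features(
    windows: list[ContextWindow], stats_from: list[ContextWindow]
) -> list[ContextWindow]:
    """Standardise ``windows`` using statistics computed on ``stats_from`` only."""
    return Standardizer().fit(stats_from).transform(windows)


def windows_to_array(windows: list[ContextWindow]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack windows into ``(X [B,N,Fd,Tn], y [B], subject_ids [B])``."""
    X = np.stack([w.features for w in windows])
    y = np.array([w.label for w in windows], dtype=int)
    subjects = np.array([w.subject_id for w in windows])
    return X, y, subjects
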
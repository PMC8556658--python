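"""Synthetic multi-subject cohorts with known structure.

The generator emulates exactly the statistical structure the staging model
assumes: a class-discriminative feature pattern shared by every subject, a
subject-specific nuisance offset (the "individual differences" that motivate
domain generalization), first-order Markov stage dynamics with a tunable
persistence, and channel noise coloured through a known ground-truth graph so
neighbouring channels correlate.  Everything is a pure function of the spec,
so identical specs give byte-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import (
    ChannelMontage,
    ContextWindow,
    EpochedRecording,
    FeatureMatrix,
    build_context_windows,
)

DEFAULT_SEED = 20240101


def ring_montage(n: int) -> ChannelMontage:
    """Synthetic montage: ``n`` electrodes equally spaced on the unit circle.

    A stand-in for a real 10-20 montage: coordinates are on the unit sphere
    (equator) and physical neighbours are adjacent on the ring.
    """
    theta = 2 * np.pi * np.arange(n) / n
    coords = np.stack([np.cos(theta), np.sin(theta), np.zeros(n)], axis=1)
    names = [f"CH{i}" for i in range(n)]
    return ChannelMontage(names, coords)


def ring_graph(n: int) -> np.ndarray:
    """Ground-truth ring adjacency (each channel coupled to its 2 neighbours)."""
    A = np.zeros((n, n))
    for i in range(n):
        A[i, (i + 1) % n] = A[(i + 1) % n, i] = 1.0
    return A


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic cohort.

    ``class_effect_size`` and ``subject_effect_size`` are expressed in units
    of the within-class noise standard deviation (which is 1 by
    construction), so e.g. ``delta = 2`` means class means are separated by
    about two noise SDs.
    """

    n_subjects: int = 8
    epochs_per_subject: int = 400
    n_channels: int = 8
    fd: int = 6
    n_classes: int = 5
    class_effect_size: float = 2.0
    subject_effect_size: float = 1.5
    transition_persistence: float = 0.7
    ground_truth_graph: np.ndarray | None = None
    seed: int = DEFAULT_SEED

    def __post_init__(self):
        if self.class_effect_size < 0 or self.subject_effect_size < 0:
            raise ValueError("effect sizes must be nonnegative")
        if not (0 <= self.transition_persistence < 1):
            raise ValueError("transition_persistence must lie in [0, 1)")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.ground_truth_graph is None:
            self.ground_truth_graph = ring_graph(self.n_channels)
        self.ground_truth_graph = np.asarray(self.ground_truth_graph, dtype=float)
        if self.ground_truth_graph.shape != (self.n_channels, self.n_channels):
            raise ValueError("ground_truth_graph must be [N, N]")
        if not np.allclose(self.ground_truth_graph, self.ground_truth_graph.T):
            raise ValueError("ground_truth_graph must be symmetric")


@dataclass
class FeatureRecording:
    """A subject's cohort slice in feature space (no raw waveform)."""

    features: list[FeatureMatrix]
    labels: np.ndarray
    subject_id: str
    montage: ChannelMontage

    @property
    def n_epochs(self) -> int:
        return len(self.features)


def noise_mixing_matrix(graph: np.ndarray) -> np.ndarray:
    """Symmetric square-root mixing matrix implied by the ground-truth graph.

    Target correlation is ``0.5 * (I + S)`` rescaled to unit diagonal, where
    ``S = D^{-1/2} A D^{-1/2}`` is the complement of the normalised Laplacian;
    it is positive semidefinite and gives positive correlation exactly along
    the graph's edges.
    """
    A = np.asarray(graph, dtype=float)
    deg = A.sum(axis=1)
    d_inv = np.where(deg > 0, 1.0 / np.sqrt(np.maximum(deg, 1e-12)), 0.0)
    S = d_inv[:, None] * A * d_inv[None, :]
    C = 0.5 * (np.eye(len(A)) + S)
    d = np.sqrt(np.diag(C))
    corr = C / np.outer(d, d)
    w, V = np.linalg.eigh(corr)
    return (V * np.sqrt(np.maximum(w, 0.0))) @ V.T


def implied_correlation(graph: np.ndarray) -> np.ndarray:
    """The channel correlation matrix the coloured noise converges to."""
    M = noise_mixing_matrix(graph)
    C = M @ M.T
    d = np.sqrt(np.diag(C))
    return C / np.outer(d, d)


def markov_labels(
    n: int, n_classes: int, persistence: float, rng: np.random.Generator
) -> np.ndarray:
    """First-order Markov chain: stay with probability ``persistence``,
    otherwise switch uniformly to one of the other classes."""
    labels = np.empty(n, dtype=int)
    labels[0] = rng.integers(n_classes)
    for t in range(1, n):
        if rng.random() < persistence:
            labels[t] = labels[t - 1]
        else:
            others = [c for c in range(n_classes) if c != labels[t - 1]]
            labels[t] = others[rng.integers(n_classes - 1)]
    return labels


def generate_cohort(spec: SyntheticSpec) -> list[FeatureRecording]:
    """Feature-space cohort: class pattern + subject offset + coloured noise."""
    root = np.random.SeedSequence(spec.seed)
    ss_class, ss_subjects = root.spawn(2)
    rng_class = np.random.default_rng(ss_class)
    class_means = rng_class.standard_normal((spec.n_classes, spec.n_channels, spec.fd))
    mix = noise_mixing_matrix(spec.ground_truth_graph)
    montage = ring_montage(spec.n_channels)

    recordings = []
    for s, ss in enumerate(ss_subjects.spawn(spec.n_subjects)):
        rng = np.random.default_rng(ss)
        offset = spec.subject_effect_size * rng.standard_normal((spec.n_channels, spec.fd))
        labels = markov_labels(
            spec.epochs_per_subject, spec.n_classes, spec.transition_persistence, rng
        )
        noise = rng.standard_normal((spec.epochs_per_subject, spec.n_channels, spec.fd))
        coloured = np.einsum("mn,tnf->tmf", mix, noise)
        feats = (
            spec.class_effect_size * class_means[labels] + offset[None] + coloured
        )
        recordings.append(
            FeatureRecording(
                features=[FeatureMatrix(feats[t]) for t in range(spec.epochs_per_subject)],
                labels=labels,
                subject_id=f"S{s:02d}",
                montage=montage,
            )
        )
    return recordings


def cohort_windows(recordings: list[FeatureRecording], d: int) -> list[ContextWindow]:
    """Context windows for every subject of a feature-space cohort."""
    windows: list[ContextWindow] = []
    for rec in recordings:
        windows.extend(build_context_windows(rec.features, rec.labels, rec.subject_id, d))
    return windows


DEFAULT_BAND_CENTERS = (2.0, 6.0, 10.0, 14.5, 22.0)  # Hz, one dominant band per class


def generate_raw_cohort(
    spec: SyntheticSpec,
    sampling_rate: float = 128.0,
    band_map: tuple[float, ...] = DEFAULT_BAND_CENTERS,
) -> list[EpochedRecording]:
    """Raw waveform cohort whose classes differ by their dominant rhythm.

    Each epoch of class ``c`` carries a sinusoid at ``band_map[c]`` Hz with
    channel-specific amplitude (plus white noise and a subject-specific gain),
    so band-wise differential entropy features are class-separable by
    construction.
    """
    if len(band_map) < spec.n_classes:
        raise ValueError("band_map must give one dominant frequency per class")
    if max(band_map[: spec.n_classes]) >= sampling_rate / 2:
        raise ValueError("band frequencies must lie below Nyquist")
    ts = int(round(30 * sampling_rate))
    t = np.arange(ts) / sampling_rate
    root = np.random.SeedSequence((spec.seed, 1))
    ss_class, ss_subjects = root.spawn(2)
    rng_class = np.random.default_rng(ss_class)
    # channel amplitude pattern per class, bounded away from zero
    amp = 1.0 + 0.5 * np.tanh(rng_class.standard_normal((spec.n_classes, spec.n_channels)))
    montage = ring_montage(spec.n_channels)

    recordings = []
    for s, ss in enumerate(ss_subjects.spawn(spec.n_subjects)):
        rng = np.random.default_rng(ss)
        gain = np.exp(0.1 * spec.subject_effect_size * rng.standard_normal(spec.n_channels))
        labels = markov_labels(
            spec.epochs_per_subject, spec.n_classes, spec.transition_persistence, rng
        )
        signal = np.empty((spec.n_channels, ts, spec.epochs_per_subject))
        for i, c in enumerate(labels):
            phase = rng.uniform(0, 2 * np.pi, size=spec.n_channels)
            osc = np.sin(2 * np.pi * band_map[c] * t[None, :] + phase[:, None])
            wave = spec.class_effect_size * amp[c][:, None] * osc
            noise = rng.standard_normal((spec.n_channels, ts))
            signal[:, :, i] = gain[:, None] * (wave + noise)
        recordings.append(
            EpochedRecording(
                signal=signal,
                sampling_rate=sampling_rate,
                labels=labels,
                subject_id=f"S{s:02d}",
                montage=montage,
            )
        )
    return recordings
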
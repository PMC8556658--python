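"""Reading and writing the package's exchange formats.

Primary format: a compressed ``.npz`` archive holding per-epoch feature
tensors, labels, subject ids and the montage.  Montages travel as two-column
text tables (name, ``x y z``); adjacency and attention summaries as
tab-delimited tables.  EDF recordings can be read through ``mne`` when it is
installed (optional dependency).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .features import ChannelMontage, EpochedRecording, FeatureMatrix, STAGE_NAMES
from .synthetic import FeatureRecording


def write_montage(path, montage: ChannelMontage) -> None:
    with open(path, "w") as fh:
        for name, (x, y, z) in zip(montage.names, montage.coords):
            fh.write(f"{name}\t{x:.8g} {y:.8g} {z:.8g}\n")


def read_montage(path) -> ChannelMontage:
    names, coords = [], []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            name, xyz = line.rstrip("\n").split("\t")
            names.append(name)
            coords.append([float(v) for v in xyz.split()])
    return ChannelMontage(names, np.array(coords))


def save_feature_cohort(path, recordings: list[FeatureRecording]) -> None:
    """Write a feature-space cohort to one compressed archive."""
    arrays = {}
    meta = {"subjects": [], "montage_names": recordings[0].montage.names}
    for rec in recordings:
        sid = rec.subject_id
        meta["subjects"].append(sid)
        arrays[f"features_{sid}"] = np.stack([fm.values for fm in rec.features])
        arrays[f"labels_{sid}"] = rec.labels
    arrays["montage_coords"] = recordings[0].montage.coords
    np.savez_compressed(
        path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays
    )


def load_feature_cohort(path) -> list[FeatureRecording]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"].tobytes()).decode())
        montage = ChannelMontage(meta["montage_names"], data["montage_coords"])
        recordings = []
        for sid in meta["subjects"]:
            feats = data[f"features_{sid}"]
            recordings.append(
                FeatureRecording(
                    features=[FeatureMatrix(f) for f in feats],
                    labels=data[f"labels_{sid}"],
                    subject_id=sid,
                    montage=montage,
                )
            )
    return recordings


def export_attention_summary(
    path,
    channel_attention: np.ndarray,  # [N, n_stages]
    channel_names: list[str],
    stage_names=STAGE_NAMES,
) -> None:
    """Per-stage channel attention table (channels x stages), tab-delimited."""
    with open(path, "w") as fh:
        fh.write("channel\t" + "\t".join(stage_names) + "\n")
        for name, row in zip(channel_names, np.asarray(channel_attention)):
            fh.write(name + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


def export_temporal_attention(path, weights: np.ndarray) -> None:
    """Temporal attention vector (length Tn) with relative epoch offsets."""
    weights = np.asarray(weights)
    d = (len(weights) - 1) // 2
    with open(path, "w") as fh:
        fh.write("offset\tweight\n")
        for off, w in zip(range(-d, d + 1), weights):
            fh.write(f"{off:+d}\t{w:.6g}\n")


def summarize_attention(pred: dict, y_true: np.ndarray, view: str = "dc") -> dict:
    """Average attention over correctly classified windows, per stage.

    Returns a channels-by-stages spatial attention table (column sums of the
    spatial map, i.e. how much attention each channel *receives*) and the
    centre-row temporal weights, the standard interpretability exports.
    """
    y_true = np.asarray(y_true, dtype=int)
    correct = pred["labels"] == y_true
    P = pred.get(f"P_{view}")
    Q = pred.get(f"Q_{view}")
    if P is None or Q is None:
        raise ValueError(f"predictions carry no attention maps for view {view!r}")
    n_stages = len(STAGE_NAMES)
    n = P.shape[-1]
    spatial = np.zeros((n, n_stages))
    tn = Q.shape[-1]
    temporal = np.zeros(tn)
    for c in range(n_stages):
        mask = correct & (y_true == c)
        if mask.any():
            spatial[:, c] = P[mask].sum(axis=1).mean(axis=0)  # column sums, averaged
    if correct.any():
        temporal = Q[correct][:, (tn - 1) // 2, :].mean(axis=0)
    return {"spatial": spatial, "temporal": temporal}


def standard_montage(names: list[str]) -> ChannelMontage:
    """10-20 montage coordinates for the given channel names (requires mne)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("standard_montage requires the optional 'mne' dependency") from exc
    montage = mne.channels.make_standard_montage("standard_1005")
    pos = montage.get_positions()["ch_pos"]
    coords = []
    for name in names:
        if name not in pos:
            raise KeyError(f"channel {name!r} not in the standard 10-20 montage")
        coords.append(pos[name])
    coords = np.asarray(coords)
    norms = np.linalg.norm(coords, axis=1, keepdims=True)
    return ChannelMontage(names, coords / norms)


def read_edf_recording(
    edf_path, hypnogram_path, channels: list[str] | None = None
) -> EpochedRecording:
    """Read an EDF recording plus a plain-text hypnogram (one stage per line).

    Stage labels may be integers 0-4 or the names Wake/N1/N2/N3/REM.
    Requires the optional ``mne`` dependency.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("read_edf_recording requires the optional 'mne' dependency") from exc
    raw = mne.io.read_raw_edf(edf_path, preload=True, verbose="error")
    if channels is not None:
        raw.pick(channels)
    fs = float(raw.info["sfreq"])
    data = raw.get_data()
    name_to_idx = {n.upper(): i for i, n in enumerate(STAGE_NAMES)}
    labels = []
    with open(hypnogram_path) as fh:
        for line in fh:
            tok = line.strip()
            if not tok:
                continue
            labels.append(int(tok) if tok.isdigit() else name_to_idx[tok.upper()])
    labels = np.asarray(labels, dtype=int)
    ts = int(round(30 * fs))
    n_epochs = min(len(labels), data.shape[1] // ts)
    signal = data[:, : n_epochs * ts].reshape(data.shape[0], n_epochs, ts).transpose(0, 2, 1)
    return EpochedRecording(
        signal=signal,
        sampling_rate=fs,
        labels=labels[:n_epochs],
        subject_id=Path(edf_path).stem,
        montage=standard_montage(list(raw.ch_names)),
    )
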
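"""Build, train and evaluate the hybrid CNN+GRU sequence-to-function predictor.

Two standing variants mirror the translation-efficiency and stability use
cases: a 4-block model for mean-ribosome-load (MRL) prediction from 5'UTRs and
a 6-block model for half-life prediction from full mRNAs (which additionally
encodes codon-frame and splice-junction tracks as two extra input channels).
Simulation benchmarks use a lighter 3-block variant.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import RNA_ALPHABET, LabeledSequenceSet, SequenceRecord
from .nn import ConvGRUNetwork, train_network

__all__ = [
    "PredictorConfig",
    "SequenceFunctionModel",
    "encode_sequence",
    "encode_dataset",
    "build_predictor",
    "train_predictor",
    "evaluate_predictor",
    "split_dataset",
    "receptive_field",
]

_BASE_INDEX = {b: i for i, b in enumerate(RNA_ALPHABET)}

#: input channel order; tracks only present in 6-channel encodings
CHANNEL_ORDER = ("A", "C", "G", "U", "frame", "splice")


@dataclass
class PredictorConfig:
    """Hyperparameters of the predictor; defaults sized for desk-scale training."""

    n_blocks: int = 4
    filters_per_block: int = 64
    kernel_width: int = 5
    pool_width: int = 2
    gru_units: int = 64
    dense_units: int = 64
    learning_rate: float = 5e-3
    weight_decay: float = 0.0
    dropout: float = 0.0
    batch_size: int = 128
    max_epochs: int = 50
    patience: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_blocks <= 8:
            raise ValueError(f"n_blocks must be in 1..8, got {self.n_blocks}")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        for name in ("filters_per_block", "kernel_width", "pool_width", "gru_units",
                     "dense_units", "batch_size", "max_epochs", "patience"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


def receptive_field(architecture: list[dict], layer_index: int) -> tuple[int, int]:
    """Receptive-field (width, stride) of the ``layer_index``-th conv layer (1-based).

    Standard recursion over the conv/pool composition: each layer of width w
    grows the field by (w-1) times the cumulative stride.
    """
    rf, jump = 1, 1
    seen_conv = 0
    for layer in architecture:
        rf += (layer["width"] - 1) * jump
        jump *= layer["stride"]
        if layer["kind"] == "conv":
            seen_conv += 1
            if seen_conv == layer_index:
                return rf, jump
    raise ValueError(f"architecture has no conv layer with index {layer_index}")


def encode_sequence(record: SequenceRecord, use_tracks: bool = False) -> np.ndarray:
    """One-hot encode a record as an L x 4 (or L x 6 with tracks) matrix.

    Channel order is (A, C, G, U[, frame, splice]).
    """
    L = len(record.sequence)
    n_channels = 6 if use_tracks else 4
    out = np.zeros((L, n_channels), dtype=np.float32)
    idx = np.fromiter((_BASE_INDEX[c] for c in record.sequence), dtype=int, count=L)
    out[np.arange(L), idx] = 1.0
    if use_tracks:
        if record.frame_track is None or record.splice_track is None:
            raise ValueError(f"record {record.id!r}: use_tracks requires frame and splice tracks")
        out[:, 4] = record.frame_track
        out[:, 5] = record.splice_track
    return out


def encode_dataset(
    dataset: LabeledSequenceSet, use_tracks: bool = False
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Encode a whole set; shorter sequences are right-padded with zero rows.

    Returns (X, valid_lengths, labels). Padding rows carry no channel signal and
    are excluded from pooling maxima and the GRU readout by ``valid_lengths``.
    """
    lengths = np.array([len(r) for r in dataset], dtype=int)
    L = int(lengths.max())
    n_channels = 6 if use_tracks else 4
    X = np.zeros((len(dataset), L, n_channels), dtype=np.float32)
    for i, rec in enumerate(dataset):
        X[i, : lengths[i]] = encode_sequence(rec, use_tracks)
    return X, lengths, dataset.labels


def encode_strings(sequences: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """One-hot encode plain RNA strings (no tracks), right-padded."""
    lengths = np.array([len(s) for s in sequences], dtype=int)
    L = int(lengths.max())
    X = np.zeros((len(sequences), L, 4), dtype=np.float32)
    for i, s in enumerate(sequences):
        idx = np.fromiter((_BASE_INDEX[c] for c in s), dtype=int, count=len(s))
        X[i, np.arange(len(s)), idx] = 1.0
    return X, lengths


class SequenceFunctionModel:
    """A trained (or untrained) predictor with a deterministic predict contract.

    Beyond prediction, the model exposes per-position post-ReLU activations of
    every convolutional block — the handle all interpretation modules use.
    """

    def __init__(self, network: ConvGRUNetwork, config: PredictorConfig, n_channels: int) -> None:
        self.network = network
        self.config = config
        self.n_channels = n_channels
        self.training_log: list[dict] = []

    @property
    def use_tracks(self) -> bool:
        return self.n_channels == 6

    def architecture(self) -> list[dict]:
        return self.network.architecture()

    def receptive_field(self, layer_index: int) -> tuple[int, int]:
        return receptive_field(self.architecture(), layer_index)

    # ------------------------------------------------------------------
    def predict(self, dataset: LabeledSequenceSet) -> np.ndarray:
        X, lengths, _ = encode_dataset(dataset, self.use_tracks)
        return self.network.predict(X, lengths)

    def predict_strings(self, sequences: list[str]) -> np.ndarray:
        if self.use_tracks:
            raise ValueError("track-encoded model cannot predict bare strings; pass records")
        X, lengths = encode_strings(sequences)
        return self.network.predict(X, lengths)

    def predict_encoded(self, X: np.ndarray, lengths: np.ndarray | None = None) -> np.ndarray:
        return self.network.predict(X, lengths)

    def conv_activations(self, dataset: LabeledSequenceSet, layer_index: int) -> np.ndarray:
        """Post-ReLU activations (n_sequences, positions, neurons) of one conv block."""
        X, lengths, _ = encode_dataset(dataset, self.use_tracks)
        return self.network.conv_activations(X, layer_index, lengths)

    def max_activation_summary(
        self, dataset: LabeledSequenceSet, layer_index: int, batch_size: int = 1024
    ) -> tuple[np.ndarray, np.ndarray]:
        """Per-sequence maximum activation and argmax position for every neuron.

        Returns (max_act, argmax_pos), each (n_sequences, n_neurons). Streaming
        over batches keeps memory flat on large datasets.
        """
        X, lengths, _ = encode_dataset(dataset, self.use_tracks)
        maxs, arg = [], []
        for i in range(0, X.shape[0], batch_size):
            act = self.network.conv_activations(X[i : i + batch_size], layer_index, lengths[i : i + batch_size])
            maxs.append(act.max(axis=1))
            arg.append(act.argmax(axis=1))
        return np.concatenate(maxs), np.concatenate(arg)

    # ------------------------------------------------------------------
    def save(self, model_dir: str | Path) -> None:
        model_dir = Path(model_dir)
        model_dir.mkdir(parents=True, exist_ok=True)
        flat = {}
        for li, layer in enumerate(self.network.layers):
            for k, v in layer.params.items():
                flat[f"{li}:{k}"] = v
        np.savez(model_dir / "params.npz", **flat)
        meta = {"config": asdict(self.config), "n_channels": self.n_channels}
        (model_dir / "config.json").write_text(json.dumps(meta, indent=2))
        pd.DataFrame(self.training_log).to_csv(model_dir / "training_log.tsv", sep="\t", index=False)

    @classmethod
    def load(cls, model_dir: str | Path) -> "SequenceFunctionModel":
        model_dir = Path(model_dir)
        meta = json.loads((model_dir / "config.json").read_text())
        config = PredictorConfig(**meta["config"])
        model = build_predictor(config, seq_length=None, n_channels=meta["n_channels"])
        arrays = np.load(model_dir / "params.npz")
        for li, layer in enumerate(model.network.layers):
            for k in layer.params:
                layer.params[k] = arrays[f"{li}:{k}"]
        log_path = model_dir / "training_log.tsv"
        if log_path.exists() and log_path.stat().st_size > 1:
            df = pd.read_csv(log_path, sep="\t")
            model.training_log = df.to_dict("records") if len(df) else []
        return model


def _shrunk_length(L: int, config: PredictorConfig) -> int:
    for _ in range(config.n_blocks):
        L = -(-(L - config.kernel_width + 1) // config.pool_width)
    return L


def build_predictor(
    config: PredictorConfig, seq_length: int | None, n_channels: int = 4
) -> SequenceFunctionModel:
    """Construct an untrained predictor; initialisation is fixed by ``config.seed``.

    ``seq_length`` (when known) is validated against the network's receptive
    field and pooling shrinkage; pass None to skip the guard (e.g. when loading).
    """
    if n_channels not in (4, 6):
        raise ValueError(f"n_channels must be 4 or 6, got {n_channels}")
    net = ConvGRUNetwork(
        n_channels=n_channels,
        n_blocks=config.n_blocks,
        filters=config.filters_per_block,
        kernel_width=config.kernel_width,
        pool_width=config.pool_width,
        gru_units=config.gru_units,
        dense_units=config.dense_units,
        seed=config.seed,
        dropout=config.dropout,
    )
    if seq_length is not None:
        rf, _ = receptive_field(net.architecture(), config.n_blocks)
        if rf > seq_length:
            raise ValueError(
                f"receptive field of last conv layer ({rf}) exceeds sequence length {seq_length}"
            )
        if _shrunk_length(seq_length, config) < 1:
            raise ValueError(
                f"no positions remain before the GRU for length {seq_length} "
                f"with {config.n_blocks} blocks"
            )
    return SequenceFunctionModel(net, config, n_channels)


def train_predictor(
    model: SequenceFunctionModel,
    train_set: LabeledSequenceSet,
    val_set: LabeledSequenceSet,
    verbose: bool = False,
) -> SequenceFunctionModel:
    """Train in place with early stopping on validation MSE; returns the model."""
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("training and validation sets must be non-empty")
    Xt, lt, yt = encode_dataset(train_set, model.use_tracks)
    Xv, lv, yv = encode_dataset(val_set, model.use_tracks)
    cfg = model.config
    model.training_log = train_network(
        model.network,
        Xt,
        yt,
        Xv,
        yv,
        learning_rate=cfg.learning_rate,
        batch_size=cfg.batch_size,
        max_epochs=cfg.max_epochs,
        patience=cfg.patience,
        seed=cfg.seed,
        weight_decay=cfg.weight_decay,
        valid_train=lt,
        valid_val=lv,
        verbose=verbose,
    )
    return model


def evaluate_predictor(model: SequenceFunctionModel, test_set: LabeledSequenceSet) -> dict:
    """Pearson r, R^2 (1 - SSres/SStot) and MSE on the raw label scale."""
    pred = model.predict(test_set)
    y = test_set.labels
    return regression_metrics(y, pred)


def regression_metrics(y: np.ndarray, pred: np.ndarray) -> dict:
    y = np.asarray(y, dtype=float)
    pred = np.asarray(pred, dtype=float)
    mse = float(np.mean((pred - y) ** 2))
    sstot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum((pred - y) ** 2)) / sstot if sstot > 0 else np.nan
    if np.std(y) == 0 or np.std(pred) == 0:
        r = np.nan
    else:
        r = float(stats.pearsonr(y, pred).statistic)
    return {"pearson_r": r, "r2": r2, "mse": mse}


def split_dataset(
    dataset: LabeledSequenceSet,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> tuple[LabeledSequenceSet, LabeledSequenceSet, LabeledSequenceSet]:
    """Deterministic train/val/test split by a seeded hash of each record id."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    edges = (fractions[0], fractions[0] + fractions[1])
    buckets: tuple[list[int], list[int], list[int]] = ([], [], [])
    for i, rec in enumerate(dataset):
        digest = hashlib.md5(f"{seed}:{rec.id}".encode()).digest()
        u = int.from_bytes(digest[:8], "big") / 2**64
        buckets[0 if u < edges[0] else 1 if u < edges[1] else 2].append(i)
    return tuple(dataset.subset(b) for b in buckets)  # type: ignore[return-value]
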
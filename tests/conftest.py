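"""Shared fixtures: synthetic datasets and a trained model reused across tests."""

from __future__ import annotations

import numpy as np
import pytest

from motifsyntax.io import LabeledSequenceSet, SequenceRecord
from motifsyntax.model import PredictorConfig, build_predictor, train_predictor

BASES = np.array(list("ACGU"))


def random_sequences(n: int, length: int, rng: np.random.Generator) -> list[str]:
    return ["".join(BASES[rng.integers(0, 4, length)]) for _ in range(n)]


def make_planted_dataset(
    n: int = 5000,
    length: int = 50,
    motif: str = "GGACUG",
    plant_fraction: float = 0.5,
    seed: int = 11,
) -> LabeledSequenceSet:
    """Random 50-mers, half carrying one planted motif; label = occurrence count."""
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        s = list(BASES[rng.integers(0, 4, length)])
        if rng.random() < plant_fraction:
            pos = int(rng.integers(0, length - len(motif) + 1))
            s[pos : pos + len(motif)] = motif
        seq = "".join(s)
        records.append(SequenceRecord(f"s{i}", seq, float(seq.count(motif))))
    return LabeledSequenceSet(records)


@pytest.fixture(scope="session")
def planted_dataset() -> LabeledSequenceSet:
    return make_planted_dataset()


@pytest.fixture(scope="session")
def planted_model(planted_dataset):
    """A 3-block model trained on the planted-6-mer dataset (shared, read-only)."""
    cfg = PredictorConfig(
        n_blocks=3, filters_per_block=32, gru_units=32, dense_units=32,
        learning_rate=5e-3, batch_size=128, max_epochs=40, patience=8, seed=7,
    )
    train = planted_dataset.subset(range(0, 4000))
    val = planted_dataset.subset(range(4000, 4500))
    model = build_predictor(cfg, seq_length=50)
    return train_predictor(model, train, val)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
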
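"""Readers and writers for sequence datasets, MEME motifs, result tables and run configs.

The package works on RNA throughout: the internal alphabet is ``ACGU`` and any
``T`` in FASTA/TSV input is silently mapped to ``U``. Coordinates are 0-based,
half-open ``[start, end)``. Labels are unit-agnostic real numbers (mean
ribosome load, half-life z-score, ...); no unit conversion is ever applied.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "RNA_ALPHABET",
    "SequenceRecord",
    "LabeledSequenceSet",
    "Motif",
    "read_sequences",
    "write_sequences",
    "read_meme_motifs",
    "write_meme_motifs",
    "read_table",
    "write_table",
    "load_config",
    "config_hash",
]

logger = logging.getLogger("motifsyntax")

RNA_ALPHABET = "ACGU"
_BASE_INDEX = {b: i for i, b in enumerate(RNA_ALPHABET)}


def normalize_sequence(seq: str, context: str = "sequence") -> str:
    """Upper-case, map T->U, and validate against the ACGU alphabet."""
    s = seq.strip().upper().replace("T", "U")
    for ch in s:
        if ch not in _BASE_INDEX:
            raise ValueError(f"non-ACGU(T) character {ch!r} in {context}")
    if not s:
        raise ValueError(f"empty sequence in {context}")
    return s


def _parse_track(value, length: int, context: str) -> np.ndarray | None:
    if value is None:
        return None
    if isinstance(value, str):
        if value == "" or value.lower() == "nan":
            return None
        arr = np.array([int(c) for c in value.strip()], dtype=np.int8)
    else:
        arr = np.asarray(value, dtype=np.int8)
    if arr.size != length:
        raise ValueError(f"track length {arr.size} != sequence length {length} in {context}")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"track values must be 0/1 in {context}")
    return arr


@dataclass
class SequenceRecord:
    """One labelled sequence, optionally with codon-frame and splice-junction tracks."""

    id: str
    sequence: str
    label: float
    frame_track: np.ndarray | None = None
    splice_track: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sequence = normalize_sequence(self.sequence, context=f"record {self.id!r}")
        self.label = float(self.label)
        self.frame_track = _parse_track(self.frame_track, len(self.sequence), f"record {self.id!r}")
        self.splice_track = _parse_track(self.splice_track, len(self.sequence), f"record {self.id!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class LabeledSequenceSet:
    """A dataset of labelled sequences; the universal input object of the package."""

    records: list[SequenceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValueError(f"duplicate sequence id {rec.id!r}")
            seen.add(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> SequenceRecord:
        return self.records[i]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=float)

    def subset(self, indices: Sequence[int]) -> "LabeledSequenceSet":
        return LabeledSequenceSet([self.records[i] for i in indices])


# maximum length for curated library/annotation motifs; discovered PPMs may be as
# wide as a deep layer's receptive field
MAX_LIBRARY_MOTIF_LEN = 30
MAX_DISCOVERED_MOTIF_LEN = 64


@dataclass
class Motif:
    """A position probability matrix over (A, C, G, U) with metadata.

    ``matrix`` has shape (L, 4) and each row is a probability distribution over
    bases. ``n_sites`` records how many aligned sites built the PPM (the
    pseudo-count base for downstream log-odds scanning).
    """

    name: str
    matrix: np.ndarray
    n_sites: int = 20
    source: str = "library"  # {discovered, library, annotation}

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4:
            raise ValueError(f"motif {self.name!r}: matrix must be (L, 4), got {m.shape}")
        max_len = MAX_DISCOVERED_MOTIF_LEN if self.source == "discovered" else MAX_LIBRARY_MOTIF_LEN
        if not 4 <= m.shape[0] <= max_len:
            raise ValueError(
                f"motif {self.name!r}: length {m.shape[0]} outside [4, {max_len}]"
            )
        if (m < 0).any():
            raise ValueError(f"motif {self.name!r}: negative probabilities")
        sums = m.sum(axis=1)
        if np.abs(sums - 1.0).max() > 1e-6:
            raise ValueError(f"motif {self.name!r}: rows do not sum to 1 (max dev {np.abs(sums-1).max():.2e})")
        self.matrix = m / sums[:, None]
        if self.n_sites < 1:
            raise ValueError(f"motif {self.name!r}: n_sites must be positive")
        if self.source not in ("discovered", "library", "annotation"):
            raise ValueError(f"motif {self.name!r}: bad source {self.source!r}")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(RNA_ALPHABET[i] for i in self.matrix.argmax(axis=1))

    def information_content(self) -> np.ndarray:
        """Per-column information content in bits against a uniform background."""
        p = np.clip(self.matrix, 1e-12, 1.0)
        return 2.0 + (p * np.log2(p)).sum(axis=1)

    def log_odds(self, pseudo: float = 0.01, background: float = 0.25) -> np.ndarray:
        """Log2-odds weight matrix for scanning, with additive pseudo-probability."""
        p = (self.matrix + pseudo) / (1.0 + 4.0 * pseudo)
        return np.log2(p / background)


# ---------------------------------------------------------------------------
# sequence dataset IO
# ---------------------------------------------------------------------------

_LABEL_TOKEN = "label="


def read_sequences(path: str | Path, format: str = "tsv") -> LabeledSequenceSet:
    """Read a labelled sequence set from FASTA (``label=<float>`` header token) or TSV.

    TSV requires columns ``id``, ``sequence``, ``label``; optional columns
    ``frame_track`` and ``splice_track`` hold 0/1 strings of the sequence length.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "fasta":
        records = []
        for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
            label = None
            for token in rec.description.split():
                if token.startswith(_LABEL_TOKEN):
                    label = float(token[len(_LABEL_TOKEN):])
            if label is None:
                raise ValueError(f"FASTA record {i + 1} ({rec.id!r}): missing 'label=' token")
            records.append(SequenceRecord(rec.id, str(rec.seq), label))
        return LabeledSequenceSet(records)
    if format == "tsv":
        # everything as strings: 0/1 tracks must keep leading zeros
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        missing = {"id", "sequence", "label"} - set(df.columns)
        if missing:
            raise ValueError(f"TSV {path} missing columns: {sorted(missing)}")
        records = []
        for i, row in enumerate(df.itertuples(index=False)):
            try:
                records.append(
                    SequenceRecord(
                        str(row.id),
                        row.sequence,
                        row.label,
                        getattr(row, "frame_track", None),
                        getattr(row, "splice_track", None),
                    )
                )
            except (ValueError, TypeError) as exc:
                raise ValueError(f"TSV {path} record {i + 1}: {exc}") from exc
        return LabeledSequenceSet(records)
    raise ValueError(f"unknown sequence format {format!r}")


def write_sequences(dataset: LabeledSequenceSet, path: str | Path, format: str = "tsv") -> None:
    path = Path(path)
    if format == "fasta":
        recs = [
            SeqRecord(Seq(r.sequence), id=r.id, description=f"label={r.label:.6g}")
            for r in dataset
        ]
        SeqIO.write(recs, str(path), "fasta")
        return
    if format == "tsv":
        rows = {
            "id": dataset.ids,
            "sequence": dataset.sequences,
            "label": [r.label for r in dataset],
        }
        if any(r.frame_track is not None for r in dataset):
            rows["frame_track"] = [
                "".join(map(str, r.frame_track)) if r.frame_track is not None else ""
                for r in dataset
            ]
        if any(r.splice_track is not None for r in dataset):
            rows["splice_track"] = [
                "".join(map(str, r.splice_track)) if r.splice_track is not None else ""
                for r in dataset
            ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        return
    raise ValueError(f"unknown sequence format {format!r}")


# ---------------------------------------------------------------------------
# MEME minimal motif format
# ---------------------------------------------------------------------------


def read_meme_motifs(path: str | Path) -> list[Motif]:
    """Parse a MEME minimal motif file (version 4 or 5) into :class:`Motif` objects.

    DNA alphabets (ACGT) are accepted and reported over ACGU; column order is
    unchanged since MEME lists both alphabets in the same core order.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not any(line.strip().startswith("MEME version") for line in lines[:5]):
        raise ValueError(f"{path}: missing 'MEME version' header")
    version_line = next(l for l in lines if l.strip().startswith("MEME version"))
    version = version_line.split()[-1].split(".")[0]
    if version not in ("4", "5"):
        raise ValueError(f"{path}: unsupported MEME version {version!r}")

    motifs: list[Motif] = []
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            parts = line.split()
            name = parts[1] if len(parts) > 1 else f"motif_{len(motifs) + 1}"
            # advance to the letter-probability header
            j = i + 1
            while j < len(lines) and not lines[j].strip().startswith("letter-probability matrix"):
                j += 1
            if j == len(lines):
                raise ValueError(f"{path}: motif {name!r} has no letter-probability matrix")
            header = lines[j].strip()
            attrs = dict(
                zip(
                    [t.rstrip("=") for t in header.split() if t.endswith("=")],
                    [t for t in header.replace("=", "= ").split()[3:] if not t.endswith("=")],
                )
            )
            width = int(attrs.get("w", 0))
            nsites = int(float(attrs.get("nsites", 20)))
            rows = []
            k = j + 1
            while k < len(lines) and len(rows) < (width or 10**9):
                stripped = lines[k].strip()
                if not stripped or stripped.startswith(("MOTIF", "URL")):
                    break
                vals = [float(x) for x in stripped.split()]
                if len(vals) != 4:
                    raise ValueError(f"{path}: motif {name!r} row {len(rows) + 1} has {len(vals)} values")
                rows.append(vals)
                k += 1
            m = np.array(rows, dtype=float)
            if width and m.shape[0] != width:
                raise ValueError(f"{path}: motif {name!r}: {m.shape[0]} rows != w={width}")
            dev = np.abs(m.sum(axis=1) - 1.0).max()
            if dev > 1e-3:
                raise ValueError(f"{path}: motif {name!r}: rows deviate from 1 by {dev:.2e}")
            if dev > 1e-9:
                warnings.warn(f"motif {name!r}: renormalizing rows (deviation {dev:.2e})")
                m = m / m.sum(axis=1, keepdims=True)
            motifs.append(Motif(name, m, n_sites=max(nsites, 1), source="annotation"))
            i = k
        else:
            i += 1
    return motifs


def write_meme_motifs(motifs: Sequence[Motif], path: str | Path) -> None:
    """Write motifs in MEME minimal format v5 over the ACGU alphabet."""
    out = ["MEME version 5", "", "ALPHABET= ACGU", "", "strands: +", ""]
    out += ["Background letter frequencies", "A 0.25 C 0.25 G 0.25 U 0.25", ""]
    for m in motifs:
        out.append(f"MOTIF {m.name}")
        out.append(
            f"letter-probability matrix: alength= 4 w= {len(m)} nsites= {m.n_sites} E= 0"
        )
        for row in m.matrix:
            out.append(" ".join(f"{x:.6f}" for x in row))
        out.append("")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# result tables and configuration
# ---------------------------------------------------------------------------


def write_table(df: pd.DataFrame, path: str | Path, config: dict | None = None) -> None:
    """Write a result table as TSV with a header comment recording provenance."""
    from motifsyntax import __version__

    chash = config_hash(config) if config is not None else "none"
    with open(path, "w") as fh:
        fh.write(f"# motifsyntax {__version__} config_hash={chash}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def load_config(path: str | Path) -> dict:
    """Load a flat YAML config; ``seed`` is required for any stochastic run."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a flat mapping")
    return cfg


def config_hash(config: dict) -> str:
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.md5(payload).hexdigest()[:12]
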
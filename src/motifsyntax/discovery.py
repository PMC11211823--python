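"""Interpret convolutional neurons into position probability matrices.

A convolutional neuron is characterised by the sequence windows (seqlets) that
activate it most strongly. A single neuron frequently responds to several
distinct patterns ("multifaceted" neurons); averaging its seqlets into one PPM
blurs them together. Here seqlets are clustered (k-means on their one-hot
encodings, with silhouette-based model selection), and each cluster becomes
its own PPM, so one neuron can yield several motifs. Deep-layer neurons have
receptive fields wide enough to span two motifs; clusters whose PPMs contain
two separate high-information subregions propose candidate motif *pairs* for
downstream epistasis testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .io import LabeledSequenceSet, Motif, RNA_ALPHABET
from .model import SequenceFunctionModel, receptive_field
from .similarity import best_match

__all__ = [
    "Seqlet",
    "NeuronInterpretation",
    "CandidatePair",
    "receptive_field",
    "extract_seqlets",
    "decouple_and_build_motifs",
    "interpret_layer",
    "candidate_pairs_from_deep_neurons",
    "unique_pairs",
]

_BASE_INDEX = {b: i for i, b in enumerate(RNA_ALPHABET)}

MIN_SEQLETS_FOR_CLUSTERING = 20


@dataclass
class Seqlet:
    """A receptive-field window that strongly activates one neuron."""

    sequence_id: str
    start: int
    end: int  # half-open
    activation: float
    subsequence: str


@dataclass
class NeuronInterpretation:
    """One neuron's motifs: (motif, seqlet-fraction weight, mean activation) per cluster."""

    layer_index: int
    neuron_index: int
    clusters: list[tuple[Motif, float, float]]


@dataclass
class CandidatePair:
    """A motif pair proposed by a single deep-neuron cluster."""

    motif_a: str
    motif_b: str
    layer_index: int
    neuron_index: int
    cluster_index: int
    score_a: float
    score_b: float


def extract_seqlets(
    model: SequenceFunctionModel,
    layer_index: int,
    neuron_index: int,
    dataset: LabeledSequenceSet,
    top_fraction: float = 0.005,
    min_seqlets: int = 200,
    summary: tuple[np.ndarray, np.ndarray] | None = None,
) -> list[Seqlet]:
    """Top activating receptive-field windows of one neuron across a dataset.

    Each sequence contributes its maximally activating window as a candidate;
    the ``top_fraction`` highest-activation candidates are kept (at least
    ``min_seqlets`` where available). A neuron that never activates returns an
    empty list. ``summary`` may carry a precomputed
    :meth:`SequenceFunctionModel.max_activation_summary` to avoid recomputing
    activations when iterating over all neurons of a layer.
    """
    rf, jump = model.receptive_field(layer_index)
    if summary is None:
        summary = model.max_activation_summary(dataset, layer_index)
    max_act, argmax_pos = summary
    acts = max_act[:, neuron_index]
    pos = argmax_pos[:, neuron_index]

    candidates: list[Seqlet] = []
    for i, rec in enumerate(dataset):
        if acts[i] <= 0.0 or len(rec.sequence) < rf:
            continue
        start = min(int(pos[i]) * jump, len(rec.sequence) - rf)
        candidates.append(
            Seqlet(rec.id, start, start + rf, float(acts[i]), rec.sequence[start : start + rf])
        )
    if not candidates:
        return []
    n_keep = max(math.ceil(top_fraction * len(candidates)), min(min_seqlets, len(candidates)))
    # activation descending; ties broken by (sequence_id, start) for determinism
    candidates.sort(key=lambda s: (-s.activation, s.sequence_id, s.start))
    return candidates[:n_keep]


def _one_hot_seqlets(seqlets: list[Seqlet]) -> np.ndarray:
    w = len(seqlets[0].subsequence)
    X = np.zeros((len(seqlets), w, 4), dtype=float)
    for i, s in enumerate(seqlets):
        for j, c in enumerate(s.subsequence):
            X[i, j, _BASE_INDEX[c]] = 1.0
    return X


def _ppm_from_onehot(X: np.ndarray) -> np.ndarray:
    """Position-wise base frequencies with a total pseudo-count of 1/sqrt(n)."""
    n = X.shape[0]
    pseudo = 1.0 / math.sqrt(n)
    counts = X.sum(axis=0) + pseudo * 0.25
    return counts / (n + pseudo)


def decouple_and_build_motifs(
    seqlets: list[Seqlet],
    max_clusters: int = 8,
    layer_index: int = 0,
    neuron_index: int = 0,
    seed: int = 0,
    selection: str = "silhouette",
) -> NeuronInterpretation:
    """Cluster a neuron's seqlets and build one PPM per cluster.

    Two model-selection policies:

    * ``"silhouette"`` (default) — k in 1..max_clusters chosen by mean
      silhouette on the one-hot encodings, with k=1 when the best silhouette
      is below 0.1 (no evidence the neuron is multifaceted). Suited to narrow
      early-layer windows, where distinct facets differ in most columns.
    * ``"fixed"`` — deliberately overcluster at k = max_clusters. Suited to
      wide deep-layer windows: random background columns dominate pairwise
      distances there and push silhouettes toward zero even when real facet
      structure exists, so silhouette selection collapses everything into one
      blurred PPM; overclustering recovers coherent facets, and surplus
      near-duplicate clusters are harmless downstream.

    Requires at least 20 seqlets.
    """
    if len(seqlets) < MIN_SEQLETS_FOR_CLUSTERING:
        raise ValueError(
            f"only {len(seqlets)} seqlets; need >= {MIN_SEQLETS_FOR_CLUSTERING} "
            "for a supported interpretation"
        )
    if selection not in ("silhouette", "fixed"):
        raise ValueError(f"bad selection policy {selection!r}")
    X = _one_hot_seqlets(seqlets)
    flat = X.reshape(len(seqlets), -1)

    n_unique = np.unique(flat, axis=0).shape[0]
    best_k, best_labels, best_sil = 1, np.zeros(len(seqlets), dtype=int), -1.0
    if selection == "fixed":
        k = min(max_clusters, n_unique, len(seqlets) // 10)
        if k >= 2:
            km = KMeans(n_clusters=k, n_init=5, random_state=seed)
            best_labels = km.fit_predict(flat)
            best_k = len(np.unique(best_labels))
    else:
        for k in range(2, min(max_clusters, n_unique) + 1):
            km = KMeans(n_clusters=k, n_init=5, random_state=seed)
            labels = km.fit_predict(flat)
            if len(np.unique(labels)) < 2:
                continue
            sil = silhouette_score(flat, labels)
            if sil > best_sil:
                best_k, best_labels, best_sil = k, labels, sil
        if best_sil < 0.1:
            best_k, best_labels = 1, np.zeros(len(seqlets), dtype=int)

    acts = np.array([s.activation for s in seqlets])
    _, best_labels = np.unique(best_labels, return_inverse=True)
    clusters = []
    for c in range(best_k):
        member = best_labels == c
        ppm = _ppm_from_onehot(X[member])
        motif = Motif(
            name=f"L{layer_index}N{neuron_index}C{c}",
            matrix=ppm,
            n_sites=int(member.sum()),
            source="discovered",
        )
        clusters.append((motif, member.mean(), float(acts[member].mean())))
    clusters.sort(key=lambda t: -t[1])
    # renumber by weight order so C0 is always the dominant facet
    renamed = []
    for c, (m, w, a) in enumerate(clusters):
        m.name = f"L{layer_index}N{neuron_index}C{c}"
        renamed.append((m, float(w), a))
    return NeuronInterpretation(layer_index, neuron_index, renamed)


def interpret_layer(
    model: SequenceFunctionModel,
    dataset: LabeledSequenceSet,
    layer_index: int,
    top_fraction: float = 0.005,
    min_seqlets: int = 200,
    max_clusters: int = 8,
    seed: int = 0,
    selection: str = "silhouette",
    summary: tuple[np.ndarray, np.ndarray] | None = None,
) -> list[NeuronInterpretation]:
    """Interpret every neuron of one conv layer; dead/under-supported neurons skipped."""
    if summary is None:
        summary = model.max_activation_summary(dataset, layer_index)
    n_neurons = summary[0].shape[1]
    out = []
    for j in range(n_neurons):
        seqlets = extract_seqlets(
            model, layer_index, j, dataset, top_fraction, min_seqlets, summary=summary
        )
        if len(seqlets) < MIN_SEQLETS_FOR_CLUSTERING:
            continue
        out.append(
            decouple_and_build_motifs(
                seqlets, max_clusters, layer_index=layer_index, neuron_index=j,
                seed=seed, selection=selection,
            )
        )
    return out


def _high_ic_subregions(
    ic: np.ndarray, ic_threshold: float, min_width: int
) -> list[tuple[int, int]]:
    """Maximal runs of informative columns (single-column dips tolerated)."""
    high = ic >= ic_threshold
    # bridge single low columns flanked by high ones
    for i in range(1, len(high) - 1):
        if not high[i] and high[i - 1] and high[i + 1]:
            high[i] = True
    regions = []
    i = 0
    while i < len(high):
        if high[i]:
            j = i
            while j < len(high) and high[j]:
                j += 1
            if j - i >= min_width and ic[i:j].mean() >= ic_threshold:
                regions.append((i, j))
            i = j
        else:
            i += 1
    return regions


def candidate_pairs_from_deep_neurons(
    interpretations: list[NeuronInterpretation],
    candidates: list[Motif],
    ic_threshold: float = 0.5,
    min_subregion: int = 4,
    min_match_score: float = 0.75,
) -> list[CandidatePair]:
    """Propose motif pairs from deep-neuron clusters containing two motif imprints.

    A pair (A, B) is emitted when one cluster's PPM holds two disjoint
    subregions of mean column information >= ``ic_threshold`` bits over at
    least ``min_subregion`` columns, and the two subregions match two distinct
    motifs from ``candidates`` (annotated or previously discovered) with best
    ungapped similarity >= ``min_match_score``.
    """
    pairs: list[CandidatePair] = []
    for interp in interpretations:
        for ci, (motif, _w, _a) in enumerate(interp.clusters):
            if motif.n_sites < 10:  # too few seqlets: pseudo-count-inflated IC
                continue
            ic = motif.information_content()
            regions = _high_ic_subregions(ic, ic_threshold, min_subregion)
            if len(regions) < 2:
                continue
            matches = []
            for (i, j) in regions:
                sub = motif.matrix[i:j]
                if sub.shape[0] < 4:
                    continue
                sub_motif = Motif(f"{motif.name}_{i}_{j}", sub, n_sites=motif.n_sites, source="discovered")
                target, _off, score = best_match(sub_motif, candidates, min_score=min_match_score)
                if target is not None:
                    matches.append((target.name, float(score)))
            names = {m[0] for m in matches}
            if len(names) < 2:
                continue
            # all distinct matched motif pairs from this cluster
            ordered = sorted(names)
            for ai in range(len(ordered)):
                for bi in range(ai + 1, len(ordered)):
                    sa = max(s for n, s in matches if n == ordered[ai])
                    sb = max(s for n, s in matches if n == ordered[bi])
                    pairs.append(
                        CandidatePair(
                            ordered[ai], ordered[bi], interp.layer_index,
                            interp.neuron_index, ci, sa, sb,
                        )
                    )
    return pairs


def unique_pairs(pairs: list[CandidatePair]) -> list[tuple[str, str]]:
    """Deduplicated, sorted (motif_a, motif_b) names across all proposals."""
    return sorted({(p.motif_a, p.motif_b) for p in pairs})


def propose_pairs(
    model: SequenceFunctionModel,
    dataset: LabeledSequenceSet,
    candidates: list[Motif],
    layers: list[int] | None = None,
    cluster_counts: tuple[int, ...] = (4, 8, 12, 16),
    seqlet_depths: tuple[int, ...] = (200, 800),
    top_fraction: float = 0.005,
    min_match_score: float = 0.75,
    seed: int = 0,
) -> list[CandidatePair]:
    """Pool deep-neuron pair proposals across layers, seqlet depths and cluster counts.

    A deep neuron's facets live at unknown granularity (pair identity x
    within-window offset), so a single cluster count under- or over-splits
    different neurons; likewise a shallow seqlet set captures only the
    dominant facet while a deep one dilutes small datasets with weak windows.
    Running the fixed-k decoupling over a small grid of both and pooling the
    deduplicated pairs makes the screen insensitive to either choice.
    """
    if layers is None:
        min_pair_span = 2 * min(len(m) for m in candidates) + 1
        layers = [
            k for k in range(1, model.config.n_blocks + 1)
            if model.receptive_field(k)[0] >= min_pair_span
        ]
    proposals: list[CandidatePair] = []
    for layer in layers:
        summary = model.max_activation_summary(dataset, layer)
        for min_seqlets in seqlet_depths:
            for k in cluster_counts:
                interps = interpret_layer(
                    model, dataset, layer, top_fraction, min_seqlets,
                    max_clusters=k, seed=seed, selection="fixed", summary=summary,
                )
                proposals.extend(
                    candidate_pairs_from_deep_neurons(
                        interps, candidates, min_match_score=min_match_score
                    )
                )
    return proposals
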
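"""Epistasis between co-occurring motif pairs by combinatorial in-silico mutagenesis.

For each sequence carrying instances of motifs A and B, four model predictions
are taken: o (intact), a (B scrambled), b (A scrambled) and n (both scrambled).
The joint effect (o - n) is compared against the sum of marginals
(a - n) + (b - n) with a two-sided Wilcoxon signed-rank test over all carrier
sequences. Combined with each motif's contribution sign, the outcome is
classified as synergistic, antagonistic, additive, or sign epistasis:

====== ====== ======================= ============
A      B      condition               interaction
====== ====== ======================= ============
pos    pos    (o-n) > (a-n)+(b-n)     synergistic
pos    pos    (o-n) < (a-n)+(b-n)     antagonistic
neg    neg    (o-n) > (a-n)+(b-n)     antagonistic
neg    neg    (o-n) < (a-n)+(b-n)     synergistic
any    any    no significant diff     additive
pos    neg    (o-n) > (a-n) signif.   sign
pos    neg    (o-n) < (b-n) signif.   sign
====== ====== ======================= ============

Scrambling replaces the instance window with uniform-random bases; several
independent scrambles are averaged so scramble noise largely cancels out of
the paired test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import LabeledSequenceSet, Motif, RNA_ALPHABET
from .model import SequenceFunctionModel

__all__ = [
    "MotifInstance",
    "MutagenesisQuadruple",
    "EpistasisResult",
    "scan_motif_instances",
    "scan_sequence",
    "scramble_instance",
    "mutagenesis_quadruple",
    "epistasis_test",
    "classify_interaction",
    "analyze_pair",
    "interaction_map",
    "plot_interaction_map",
]

logger = logging.getLogger("motifsyntax")

_BASE_INDEX = {b: i for i, b in enumerate(RNA_ALPHABET)}

MIN_QUADRUPLES = 10
MIN_TOTAL_IC_BITS = 2.0


@dataclass
class MotifInstance:
    sequence_id: str
    motif_name: str
    start: int
    end: int  # half-open; end - start == motif length
    match_score: float  # log2-odds of the window


@dataclass
class MutagenesisQuadruple:
    sequence_id: str
    o: float
    a: float
    b: float
    n: float


@dataclass
class EpistasisResult:
    motif_a: str
    motif_b: str
    sign_a: str  # {positive, negative}
    sign_b: str
    n_instances: int
    p_value: float
    direction: str  # {joint_greater, joint_smaller, none}
    interaction_class: str  # {synergistic, antagonistic, additive, sign}
    both_sign_rules: bool = False  # mixed signs with both one-sided rules triggered
    median_deviation: float = np.nan  # median of (o-n) - [(a-n)+(b-n)], label units


def _seq_to_idx(seq: str) -> np.ndarray:
    return np.fromiter((_BASE_INDEX[c] for c in seq), dtype=int, count=len(seq))


def scan_sequence(
    sequence: str, motif: Motif, threshold_fraction: float = 0.8
) -> list[tuple[int, float]]:
    """(start, score) of log-odds matches >= threshold_fraction * max score."""
    w = len(motif)
    if w > len(sequence):
        return []
    lom = motif.log_odds()
    max_score = float(lom.max(axis=1).sum())
    idx = _seq_to_idx(sequence)
    windows = np.lib.stride_tricks.sliding_window_view(idx, w)  # (P, w)
    scores = lom[np.arange(w), windows].sum(axis=1)
    keep = np.flatnonzero(scores >= threshold_fraction * max_score)
    return [(int(p), float(scores[p])) for p in keep]


def _merge_overlaps(hits: list[tuple[int, float]], width: int) -> list[tuple[int, float]]:
    """Among mutually overlapping matches keep only the best-scoring one."""
    merged: list[tuple[int, float]] = []
    for start, score in sorted(hits):
        if merged and start < merged[-1][0] + width:
            if score > merged[-1][1]:
                merged[-1] = (start, score)
        else:
            merged.append((start, score))
    return merged


def scan_motif_instances(
    dataset: LabeledSequenceSet, motif: Motif, threshold_fraction: float = 0.8
) -> list[MotifInstance]:
    """Log-odds scan of one motif over every sequence (uniform 0.25 background).

    Overlapping matches of the same motif are merged keeping the best score.
    Degenerate motifs (total information below 2 bits) match everywhere and are
    rejected.
    """
    total_ic = float(motif.information_content().sum())
    if total_ic < MIN_TOTAL_IC_BITS:
        raise ValueError(
            f"motif {motif.name!r} has {total_ic:.2f} bits of information (< {MIN_TOTAL_IC_BITS}); "
            "scanning would match everywhere"
        )
    out = []
    w = len(motif)
    for rec in dataset:
        hits = _merge_overlaps(scan_sequence(rec.sequence, motif, threshold_fraction), w)
        out.extend(
            MotifInstance(rec.id, motif.name, s, s + w, score) for s, score in hits
        )
    return out


def scramble_instance(
    sequence: str, instance: MotifInstance, n_replicates: int, seed: int
) -> list[str]:
    """Replace the instance window with uniform-random bases, ``n_replicates`` times."""
    if not 0 <= instance.start < instance.end <= len(sequence):
        raise ValueError(f"instance [{instance.start}, {instance.end}) outside sequence")
    rng = np.random.default_rng(seed)
    w = instance.end - instance.start
    out = []
    for _ in range(n_replicates):
        rand = "".join(RNA_ALPHABET[i] for i in rng.integers(0, 4, w))
        out.append(sequence[: instance.start] + rand + sequence[instance.end :])
    return out


def _scramble_windows(
    sequence: str, windows: list[tuple[int, int]], n_replicates: int, rng: np.random.Generator
) -> list[str]:
    out = []
    for _ in range(n_replicates):
        s = list(sequence)
        for start, end in windows:
            for i in range(start, end):
                s[i] = RNA_ALPHABET[rng.integers(0, 4)]
        out.append("".join(s))
    return out


def mutagenesis_quadruple(
    model: SequenceFunctionModel,
    sequence: str,
    instance_a: MotifInstance,
    instance_b: MotifInstance,
    n_replicates: int = 8,
    seed: int = 0,
) -> MutagenesisQuadruple:
    """Model predictions o/a/b/n for one sequence; scrambles averaged over replicates."""
    if instance_a.start < instance_b.end and instance_b.start < instance_a.end:
        raise ValueError(
            f"instances of {instance_a.motif_name} and {instance_b.motif_name} overlap "
            f"in sequence {instance_a.sequence_id}"
        )
    rng = np.random.default_rng(seed)
    wa = (instance_a.start, instance_a.end)
    wb = (instance_b.start, instance_b.end)
    seqs = (
        [sequence]
        + _scramble_windows(sequence, [wb], n_replicates, rng)  # a: B scrambled
        + _scramble_windows(sequence, [wa], n_replicates, rng)  # b: A scrambled
        + _scramble_windows(sequence, [wa, wb], n_replicates, rng)  # n: both
    )
    preds = model.predict_strings(seqs)
    o = float(preds[0])
    a = float(preds[1 : 1 + n_replicates].mean())
    b = float(preds[1 + n_replicates : 1 + 2 * n_replicates].mean())
    n = float(preds[1 + 2 * n_replicates :].mean())
    return MutagenesisQuadruple(instance_a.sequence_id, o, a, b, n)


def _signed_rank(diffs: np.ndarray, alpha: float) -> tuple[float, str]:
    d = np.asarray(diffs, dtype=float)
    nz = d[d != 0.0]
    if nz.size == 0:
        return 1.0, "none"
    p = float(stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided").pvalue)
    med = float(np.median(d))
    if p <= alpha and med != 0.0:
        return p, "joint_greater" if med > 0 else "joint_smaller"
    return p, "none"


def epistasis_test(
    quadruples: list[MutagenesisQuadruple], alpha: float = 0.05
) -> tuple[float, str]:
    """Two-sided Wilcoxon signed-rank of (o-n) against (a-n)+(b-n), paired by sequence."""
    if len(quadruples) < MIN_QUADRUPLES:
        raise ValueError(f"need >= {MIN_QUADRUPLES} quadruples, got {len(quadruples)}")
    d = np.array([(q.o - q.n) - ((q.a - q.n) + (q.b - q.n)) for q in quadruples])
    return _signed_rank(d, alpha)


def classify_interaction(
    sign_a: str,
    sign_b: str,
    direction: str,
    direction_vs_a: str | None = None,
    direction_vs_b: str | None = None,
) -> tuple[str, bool]:
    """Interaction class from contribution signs and test direction(s).

    Same-sign pairs use ``direction`` (joint vs sum of marginals). Mixed-sign
    pairs use the two one-directional comparisons (o-n) vs (a-n) and
    (o-n) vs (b-n), passed with the convention that motif A is the
    positive-effect motif; callers with A negative and B positive should swap.
    Returns (class, both_sign_rules_triggered).
    """
    for s in (sign_a, sign_b):
        if s not in ("positive", "negative"):
            raise ValueError(f"sign must be positive/negative, got {s!r}")
    if direction not in ("joint_greater", "joint_smaller", "none"):
        raise ValueError(f"bad direction {direction!r}")
    if sign_a == sign_b:
        if direction == "none":
            return "additive", False
        if sign_a == "positive":
            return ("synergistic" if direction == "joint_greater" else "antagonistic"), False
        return ("antagonistic" if direction == "joint_greater" else "synergistic"), False
    # mixed signs: A positive, B negative by convention
    if direction_vs_a is None or direction_vs_b is None:
        raise ValueError("mixed-sign classification needs direction_vs_a and direction_vs_b")
    rule_a = direction_vs_a == "joint_greater"  # (o-n) significantly > (a-n)
    rule_b = direction_vs_b == "joint_smaller"  # (o-n) significantly < (b-n)
    if rule_a or rule_b:
        return "sign", bool(rule_a and rule_b)
    return "additive", False


def _pick_disjoint_instances(
    hits_a: list[MotifInstance], hits_b: list[MotifInstance]
) -> tuple[MotifInstance, MotifInstance] | None:
    """Best-scoring disjoint (A, B) instance pair within one sequence, if any."""
    best = None
    best_key = -np.inf
    for ia in hits_a:
        for ib in hits_b:
            if ia.start < ib.end and ib.start < ia.end:
                continue
            key = min(ia.match_score, ib.match_score)
            if key > best_key:
                best, best_key = (ia, ib), key
    return best


def analyze_pair(
    model: SequenceFunctionModel,
    dataset: LabeledSequenceSet,
    motif_a: Motif,
    motif_b: Motif,
    sign_a: str | None = None,
    sign_b: str | None = None,
    threshold_fraction: float = 0.8,
    n_replicates: int = 8,
    alpha: float = 0.05,
    max_sequences: int = 200,
    seed: int = 0,
) -> EpistasisResult | None:
    """Full mutagenesis epistasis analysis of one motif pair over a dataset.

    Sequences carrying disjoint instances of both motifs are collected (capped
    at ``max_sequences``, keeping the best-matching carriers), the o/a/b/n
    quadruples are predicted in one batch, and the pair is classified. Returns
    None when fewer than 10 carrier sequences exist.

    ``sign_a``/``sign_b`` may come from contribution analysis; when None, each
    motif's sign is inferred from its own mutagenesis marginal — a Wilcoxon
    signed-rank test of a-n (respectively b-n) against zero — which measures
    the effect direction directly and is robust to confounded dataset
    composition. A motif whose marginal is not significantly nonzero yields
    None (no classifiable signs).
    """
    # normalize mixed-sign convention: A is the positive-effect motif
    if sign_a == "negative" and sign_b == "positive":
        motif_a, motif_b = motif_b, motif_a
        sign_a, sign_b = sign_b, sign_a
    by_seq_a: dict[str, list[MotifInstance]] = {}
    for inst in scan_motif_instances(dataset, motif_a, threshold_fraction):
        by_seq_a.setdefault(inst.sequence_id, []).append(inst)
    by_seq_b: dict[str, list[MotifInstance]] = {}
    for inst in scan_motif_instances(dataset, motif_b, threshold_fraction):
        by_seq_b.setdefault(inst.sequence_id, []).append(inst)

    carriers = []
    seq_by_id = {rec.id: rec.sequence for rec in dataset}
    for sid in by_seq_a.keys() & by_seq_b.keys():
        pair = _pick_disjoint_instances(by_seq_a[sid], by_seq_b[sid])
        if pair is None:
            logger.debug("pair (%s, %s): only overlapping instances in %s; skipped",
                         motif_a.name, motif_b.name, sid)
            continue
        carriers.append((min(pair[0].match_score, pair[1].match_score), sid, pair))
    if len(carriers) < MIN_QUADRUPLES:
        logger.info("pair (%s, %s): only %d carrier sequences; not testable",
                    motif_a.name, motif_b.name, len(carriers))
        return None
    carriers.sort(key=lambda t: (-t[0], t[1]))
    carriers = carriers[:max_sequences]

    rng = np.random.default_rng(seed)
    all_seqs: list[str] = []
    for _, sid, (ia, ib) in carriers:
        seq = seq_by_id[sid]
        wa, wb = (ia.start, ia.end), (ib.start, ib.end)
        all_seqs.append(seq)
        all_seqs += _scramble_windows(seq, [wb], n_replicates, rng)
        all_seqs += _scramble_windows(seq, [wa], n_replicates, rng)
        all_seqs += _scramble_windows(seq, [wa, wb], n_replicates, rng)
    preds = model.predict_strings(all_seqs)
    per_seq = 1 + 3 * n_replicates
    quads = []
    for i, (_, sid, _) in enumerate(carriers):
        block = preds[i * per_seq : (i + 1) * per_seq]
        quads.append(
            MutagenesisQuadruple(
                sid,
                float(block[0]),
                float(block[1 : 1 + n_replicates].mean()),
                float(block[1 + n_replicates : 1 + 2 * n_replicates].mean()),
                float(block[1 + 2 * n_replicates :].mean()),
            )
        )

    if sign_a is None or sign_b is None:
        inferred = []
        for marg in (np.array([q.a - q.n for q in quads]), np.array([q.b - q.n for q in quads])):
            p_m, dir_m = _signed_rank(marg, alpha)
            if dir_m == "none":
                logger.info(
                    "pair (%s, %s): a motif's mutagenesis marginal is not significant; "
                    "signs undetermined", motif_a.name, motif_b.name)
                return None
            inferred.append("positive" if dir_m == "joint_greater" else "negative")
        sign_a, sign_b = inferred
        if sign_a == "negative" and sign_b == "positive":
            motif_a, motif_b = motif_b, motif_a
            sign_a, sign_b = sign_b, sign_a
            quads = [MutagenesisQuadruple(q.sequence_id, q.o, q.b, q.a, q.n) for q in quads]

    dev = np.array([(q.o - q.n) - ((q.a - q.n) + (q.b - q.n)) for q in quads])
    if sign_a == sign_b:
        p, direction = epistasis_test(quads, alpha)
        cls, both = classify_interaction(sign_a, sign_b, direction)
    else:
        p_a, dir_a = _signed_rank(np.array([q.o - q.a for q in quads]), alpha)
        p_b, dir_b = _signed_rank(np.array([q.o - q.b for q in quads]), alpha)
        cls, both = classify_interaction(sign_a, sign_b, "none", dir_a, dir_b)
        triggered = []
        if dir_a == "joint_greater":
            triggered.append(p_a)
        if dir_b == "joint_smaller":
            triggered.append(p_b)
        p = min(triggered) if triggered else min(p_a, p_b)
        direction = "none"
    return EpistasisResult(
        motif_a.name, motif_b.name, sign_a, sign_b, len(quads), p, direction, cls,
        both_sign_rules=both, median_deviation=float(np.median(dev)),
    )


def interaction_map(
    results: list[EpistasisResult], motif_names: list[str] | None = None
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Symmetric motif-by-motif matrix of interaction classes, plus class tallies.

    Pairs never proposed are NaN; tested-but-additive pairs carry "additive",
    so absence and additivity stay distinguishable.
    """
    if motif_names is None:
        motif_names = sorted({n for r in results for n in (r.motif_a, r.motif_b)})
    mat = pd.DataFrame(np.nan, index=motif_names, columns=motif_names, dtype=object)
    counts: dict[str, int] = {}
    for r in results:
        mat.loc[r.motif_a, r.motif_b] = r.interaction_class
        mat.loc[r.motif_b, r.motif_a] = r.interaction_class
        counts[r.interaction_class] = counts.get(r.interaction_class, 0) + 1
    return mat, counts


def plot_interaction_map(results: list[EpistasisResult], path: str, motif_names=None) -> None:
    """Render the interaction map to an image file (dots coloured by class)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mat, counts = interaction_map(results, motif_names)
    names = list(mat.index)
    colors = {"synergistic": "tab:red", "antagonistic": "tab:purple",
              "additive": "tab:blue", "sign": "tab:orange"}
    fig, ax = plt.subplots(figsize=(1 + 0.5 * len(names), 1 + 0.5 * len(names)))
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            v = mat.iloc[i, j]
            if isinstance(v, str):
                ax.scatter(j, i, s=120, c=colors.get(v, "gray"))
    ax.set_xticks(range(len(names)), names, rotation=90)
    ax.set_yticks(range(len(names)), names)
    ax.set_xlim(-0.5, len(names) - 0.5)
    ax.set_ylim(len(names) - 0.5, -0.5)
    handles = [plt.Line2D([], [], marker="o", ls="", color=c, label=f"{k} (n={counts.get(k, 0)})")
               for k, c in colors.items() if counts.get(k)]
    ax.legend(handles=handles, bbox_to_anchor=(1.02, 1), loc="upper left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
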
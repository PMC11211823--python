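"""Does a neuron's motif raise or lower the predicted mRNA property?

The dataset is split by whether each sequence activates the neuron (its
maximum positional activation exceeds a fraction gamma of the dataset-wide
maximum for that neuron). The labels of the two groups are compared with a
two-sided Mann–Whitney U test — labels such as mean ribosome load are not
Gaussian, so a rank test is used rather than a t-test — and Benjamini–
Hochberg correction is applied across all neurons tested in one run. The
resulting direction (positive / negative / none) is an association between
neuron activation and the label, not a causal claim.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import LabeledSequenceSet
from .model import SequenceFunctionModel

__all__ = [
    "ContributionResult",
    "activation_split",
    "contribution_test",
    "analyze_layer_contributions",
]

MIN_GROUP_SIZE = 10


@dataclass
class ContributionResult:
    layer_index: int
    neuron_index: int
    n_activating: int
    n_nonactivating: int
    effect_direction: str  # {positive, negative, none}
    p_value: float
    q_value: float
    median_difference: float
    underpowered: bool = False


def activation_split(
    model: SequenceFunctionModel,
    layer_index: int,
    neuron_index: int,
    dataset: LabeledSequenceSet,
    gamma: float = 0.5,
    summary: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[list[str], list[str]]:
    """Partition sequence ids into (activating, non-activating) for one neuron.

    A sequence activates the neuron iff its maximum positional activation
    exceeds ``gamma`` times the dataset-wide maximum activation of that neuron.
    The post-ReLU ">0" criterion alone is too permissive in deep layers, hence
    the relative threshold.
    """
    if not 0.0 < gamma < 1.0:
        raise ValueError(f"gamma must be in (0, 1), got {gamma}")
    if summary is None:
        summary = model.max_activation_summary(dataset, layer_index)
    acts = summary[0][:, neuron_index]
    top = acts.max()
    if top <= 0.0:
        raise ValueError(
            f"neuron {neuron_index} of layer {layer_index} never activates (dead neuron)"
        )
    activating = [rec.id for rec, a in zip(dataset, acts) if a > gamma * top]
    nonactivating = [rec.id for rec, a in zip(dataset, acts) if a <= gamma * top]
    return activating, nonactivating


def contribution_test(
    split: tuple[list[str], list[str]],
    labels: dict[str, float],
    alpha: float = 0.05,
    layer_index: int = 0,
    neuron_index: int = 0,
) -> ContributionResult:
    """Mann–Whitney U comparison of labels between the two activation groups.

    The returned ``q_value`` equals the raw p-value; when several neurons are
    tested together, :func:`analyze_layer_contributions` replaces it with the
    BH-adjusted value and re-derives the direction.
    """
    act_ids, non_ids = split
    ya = np.array([labels[i] for i in act_ids], dtype=float)
    yn = np.array([labels[i] for i in non_ids], dtype=float)
    if len(ya) < MIN_GROUP_SIZE or len(yn) < MIN_GROUP_SIZE:
        return ContributionResult(
            layer_index, neuron_index, len(ya), len(yn),
            "none", np.nan, np.nan, np.nan, underpowered=True,
        )
    med_diff = float(np.median(ya) - np.median(yn))
    if np.all(ya[:, None] == yn[None, :]):
        p = 1.0
    else:
        p = float(stats.mannwhitneyu(ya, yn, alternative="two-sided").pvalue)
    direction = _direction(med_diff, p, alpha)
    return ContributionResult(
        layer_index, neuron_index, len(ya), len(yn), direction, p, p, med_diff
    )


def _direction(median_difference: float, q: float, alpha: float) -> str:
    if not np.isfinite(q) or q > alpha or median_difference == 0.0:
        return "none"
    return "positive" if median_difference > 0 else "negative"


def analyze_layer_contributions(
    model: SequenceFunctionModel,
    dataset: LabeledSequenceSet,
    layer_index: int,
    neuron_indices: list[int] | None = None,
    gamma: float = 0.5,
    alpha: float = 0.05,
) -> list[ContributionResult]:
    """Contribution test for every (requested) neuron of a layer, BH-corrected."""
    summary = model.max_activation_summary(dataset, layer_index)
    n_neurons = summary[0].shape[1]
    if neuron_indices is None:
        neuron_indices = list(range(n_neurons))
    labels = {rec.id: rec.label for rec in dataset}
    results = []
    for j in neuron_indices:
        if summary[0][:, j].max() <= 0.0:
            results.append(
                ContributionResult(layer_index, j, 0, len(dataset), "none", np.nan, np.nan, np.nan, True)
            )
            continue
        split = activation_split(model, layer_index, j, dataset, gamma, summary=summary)
        results.append(contribution_test(split, labels, alpha, layer_index, j))
    tested = [r for r in results if np.isfinite(r.p_value)]
    if tested:
        _, qvals, _, _ = multipletests([r.p_value for r in tested], method="fdr_bh")
        for r, q in zip(tested, qvals):
            r.q_value = float(q)
            r.effect_direction = _direction(r.median_difference, r.q_value, alpha)
    return results
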
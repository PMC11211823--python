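"""Synthetic dataset generation, ground-truth labelling, uAUG filtering, scoring."""

import numpy as np
import pytest

from motifsyntax.interaction import scan_sequence
from motifsyntax.io import LabeledSequenceSet, SequenceRecord
from motifsyntax.simulation import (
    Interaction,
    SimulationSpec,
    bimodality,
    default_library,
    dense_interactions,
    filter_uaug,
    generate_dataset,
    generate_designed_dataset,
    generate_random_dataset,
    ground_truth_label,
    score_recovery,
)
from tests.conftest import BASES


def _spec(**kw):
    defaults = dict(dataset_kind="random", n_sequences=500, seed=3)
    defaults.update(kw)
    return SimulationSpec(**defaults)


class TestSpecValidation:
    def test_duplicate_interaction_pairs_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            _spec(interactions=[
                Interaction("m6A", "PUF", "synergistic"),
                Interaction("PUF", "m6A", "antagonistic"),
            ])

    def test_unknown_motif_rejected(self):
        with pytest.raises(ValueError, match="unknown motif"):
            _spec(interactions=[Interaction("m6A", "nope", "synergistic")])

    def test_bad_interaction_type_rejected(self):
        with pytest.raises(ValueError, match="type"):
            Interaction("a", "b", "mystery")

    def test_dense_interactions_cover_all_pairs(self):
        dense = dense_interactions()
        assert len(dense) == 6
        assert len({it.pair for it in dense}) == 6
        assert {it.type for it in dense} == {"synergistic", "antagonistic"}


class TestRandomDataset:
    def test_base_composition_uniform(self):
        ds, _ = generate_random_dataset(_spec(n_sequences=2000, seq_length=50))
        counts = np.zeros(4)
        for rec in ds:
            for c in rec.sequence:
                counts["ACGU".index(c)] += 1
        n = counts.sum()
        assert n == 100_000
        se = np.sqrt(0.25 * 0.75 / n)
        assert np.all(np.abs(counts / n - 0.25) < 3 * se + 1e-9)

    def test_expected_5mer_occurrence_rate(self):
        """A fixed 5-mer appears ~46/4^5 ~ 0.045 times per 50-mer; two fixed
        motifs almost never co-occur — the designed/random contrast mechanism."""
        ds, _ = generate_random_dataset(_spec(n_sequences=4000, seq_length=50, seed=8))
        count = sum(rec.sequence.count("GGACU") for rec in ds)
        rate = count / len(ds)
        assert rate == pytest.approx(46 / 4**5, abs=3 * np.sqrt(0.045 / len(ds)))
        both = sum(
            1 for rec in ds if "GGACUG" in rec.sequence and "UGUAUAUA" in rec.sequence
        )
        assert both <= 1

    def test_seed_determinism(self):
        a, _ = generate_random_dataset(_spec(seed=7))
        b, _ = generate_random_dataset(_spec(seed=7))
        assert a.sequences == b.sequences
        assert np.array_equal(a.labels, b.labels)


class TestDesignedDataset:
    def test_every_sequence_has_two_planted_instances(self):
        ds, truth = generate_designed_dataset(_spec(dataset_kind="designed", n_sequences=300))
        for sid, planted in truth.planted.items():
            assert len(planted) == 2
            names = {p.motif_name for p in planted}
            assert len(names) == 2

    def test_pair_balance(self):
        n = 3000
        ds, truth = generate_designed_dataset(_spec(dataset_kind="designed", n_sequences=n))
        counts = {}
        for planted in truth.planted.values():
            key = tuple(sorted(p.motif_name for p in planted))
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 6
        expected = n / 6
        se = np.sqrt(n * (1 / 6) * (5 / 6))
        for c in counts.values():
            assert abs(c - expected) < 3 * se

    def test_planted_instance_rediscovery_matches_exact_draw_rate(self):
        """A planted instance is rediscovered at its position iff its sampled
        string passes the scan threshold; at 0.95 consensus probability and a
        0.8 log-odds-fraction cutoff only mismatch-free draws pass, so the
        rediscovery rate per instance equals the exact-draw probability
        (enumeration oracle), not ~1 — the misses are the dataset's natural
        single-motif examples."""
        ds, truth = generate_designed_dataset(_spec(dataset_kind="designed", n_sequences=600, seed=21))
        by_name = {m.name: m for m in default_library()}
        found, total = {}, {}
        for rec in ds:
            for p in truth.planted[rec.id]:
                motif = by_name[p.motif_name]
                hits = scan_sequence(rec.sequence, motif, 0.8)
                total[p.motif_name] = total.get(p.motif_name, 0) + 1
                if any(s == p.start for s, _ in hits):
                    found[p.motif_name] = found.get(p.motif_name, 0) + 1
        for name, motif in by_name.items():
            # oracle: probability that a per-column draw passes the threshold
            lom = motif.log_odds()
            cutoff = 0.8 * lom.max(axis=1).sum()
            pass_prob = 1.0
            # columns are independent; enumerate best/worst per column:
            # a single mismatch already falls below the cutoff for these PPMs
            exact = float(np.prod(motif.matrix.max(axis=1)))
            one_mismatch_score = lom.max(axis=1).sum() - lom[0].max() + sorted(lom[0])[-2]
            assert one_mismatch_score < cutoff
            rate = found.get(name, 0) / total[name]
            se = np.sqrt(exact * (1 - exact) / total[name])
            assert rate == pytest.approx(exact, abs=4 * se)

    def test_planted_windows_disjoint_and_in_bounds(self):
        ds, truth = generate_designed_dataset(_spec(dataset_kind="designed", n_sequences=200))
        by_name = {m.name: len(m) for m in default_library()}
        for rec in ds:
            spans = sorted(
                (p.start, p.start + by_name[p.motif_name]) for p in truth.planted[rec.id]
            )
            assert spans[0][1] <= spans[1][0]
            assert 0 <= spans[0][0] and spans[1][1] <= len(rec.sequence)


class TestGroundTruthLabel:
    def test_empty_presence_is_zero(self):
        assert ground_truth_label(set(), _spec(noise_sd=0.0)) == 0.0

    def test_synergistic_pair_with_unit_effects(self):
        spec = _spec(interactions=[Interaction("m6A", "PUF", "synergistic")], noise_sd=0.0)
        assert ground_truth_label({"m6A", "PUF"}, spec) == 3.0
        spec_ant = _spec(interactions=[Interaction("m6A", "PUF", "antagonistic")], noise_sd=0.0)
        assert ground_truth_label({"m6A", "PUF"}, spec_ant) == 1.0

    def test_moment_check_on_designed_labels(self):
        """Mean label of pair carriers minus single-motif sums recovers s_ij*e_ij."""
        spec = _spec(
            dataset_kind="designed", n_sequences=6000,
            interactions=[Interaction("m6A", "PUF", "synergistic", 1.0)], seed=5,
        )
        ds, truth = generate_designed_dataset(spec)
        pair_labels, single = {}, {}
        for rec in ds:
            present = truth.present[rec.id]
            if present == {"m6A", "PUF"}:
                pair_labels.setdefault("both", []).append(rec.label)
            elif present == {"m6A"} or present == {"PUF"}:
                single.setdefault(tuple(present), []).append(rec.label)
            elif not present:
                pair_labels.setdefault("none", []).append(rec.label)
        both = np.mean(pair_labels["both"])
        base = np.mean(pair_labels.get("none", [0.0]))
        sum_singles = sum(np.mean(v) for v in single.values())
        # E[both] - E[m6A only] - E[PUF only] + E[none] = s_ij * e_ij = +1
        tol = 4 * spec.noise_sd / np.sqrt(min(len(v) for v in single.values()))
        assert both - sum_singles + base == pytest.approx(1.0, abs=max(tol, 0.15))


class TestUaugFilter:
    def test_exact_toy_counts(self):
        seqs = ["CCAUGCC", "CCACGCC", "AUGAAAA", "GGGGGGG", "AAAUGAA",
                "CCCCCCC", "UUUUUUU", "GAUGGGG", "ACGUACG", "UGAUGCA"]
        ds = LabeledSequenceSet([SequenceRecord(f"s{i}", s, 0.0) for i, s in enumerate(seqs)])
        kept, removed = filter_uaug(ds)
        assert removed == 5
        assert len(kept) == 5
        assert all("AUG" not in r.sequence for r in kept)

    def test_random_50mer_survival_fraction(self):
        """Exact AUG-free probability for i.i.d. uniform 50-mers.

        The naive independence approximation (1 - 1/64)^48 ~ 0.47 overstates
        survival; the exact value from the match-progress automaton is 0.4583,
        and the empirical fraction must agree to binomial accuracy.
        """
        T = np.array([[3 / 4, 1 / 4, 0], [2 / 4, 1 / 4, 1 / 4], [2 / 4, 1 / 4, 0]])
        v = np.array([1.0, 0.0, 0.0])
        for _ in range(50):
            v = v @ T
        exact = v.sum()
        assert exact == pytest.approx(0.45826, abs=1e-5)

        rng = np.random.default_rng(12)
        n = 100_000
        codes = rng.integers(0, 4, size=(n, 50))
        # AUG = codes (0, 3, 2); vectorized window test
        hits = (codes[:, :-2] == 0) & (codes[:, 1:-1] == 3) & (codes[:, 2:] == 2)
        survived = float((~hits.any(axis=1)).mean())
        se = np.sqrt(exact * (1 - exact) / n)
        assert survived == pytest.approx(exact, abs=3 * se)

    def test_uaug_shortcut_creates_then_loses_bimodality(self):
        spec = _spec(n_sequences=4000, uaug_penalty=2.0, seed=9)
        ds, _ = generate_random_dataset(spec)
        before = bimodality(ds.labels)
        kept, removed = filter_uaug(ds)
        after = bimodality(kept.labels)
        assert 0.3 < removed / len(ds) < 0.8
        # two well-separated modes before; the lower mode vanishes after
        assert before["delta_bic"] > 100
        assert before["means"][1] - before["means"][0] == pytest.approx(2.0, abs=0.3)
        assert after["delta_bic"] < before["delta_bic"] / 10
        assert after["means"][1] - after["means"][0] < 0.5


class TestRecoveryScoring:
    def test_identity_and_zero_and_half(self):
        truth = {("a", "b"): "synergistic", ("c", "d"): "antagonistic"}
        assert score_recovery(truth, dict(truth)) == 1.0
        assert score_recovery(truth, {}) == 0.0
        assert score_recovery(truth, {("a", "b"): "synergistic"}) == 0.5
        # recovered with the wrong class does not count
        assert score_recovery(truth, {("a", "b"): "antagonistic"}) == 0.0

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError):
            score_recovery({}, {})


def test_generate_dataset_dispatch():
    ds_r, _ = generate_dataset(_spec())
    ds_d, _ = generate_dataset(_spec(dataset_kind="designed"))
    assert len(ds_r) == len(ds_d) == 500
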
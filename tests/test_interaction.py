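"""Mutagenesis epistasis: scanning, scrambling, paired testing, classification."""

import itertools

import numpy as np
import pytest

from motifsyntax.interaction import (
    MotifInstance,
    MutagenesisQuadruple,
    analyze_pair,
    classify_interaction,
    epistasis_test,
    interaction_map,
    mutagenesis_quadruple,
    scan_motif_instances,
    scan_sequence,
    scramble_instance,
)
from motifsyntax.io import LabeledSequenceSet, Motif, SequenceRecord
from motifsyntax.simulation import consensus_motif
from tests.conftest import BASES


def _ds(seqs):
    return LabeledSequenceSet([SequenceRecord(f"s{i}", s, 0.0) for i, s in enumerate(seqs)])


class TestScan:
    def test_embedded_consensus_found_at_position(self, rng):
        motif = consensus_motif("m", "GGACUG")
        background = "".join(BASES[rng.integers(0, 4, 50)])
        seq = background[:17] + "GGACUG" + background[23:]
        hits = scan_motif_instances(_ds([seq]), motif)
        assert any(h.start == 17 for h in hits)

    def test_m6a_positions_in_tandem_sequence(self):
        # two occurrences by direct inspection of the string
        m6a = consensus_motif("m6A5", "GGACU")
        hits = scan_motif_instances(_ds(["GGACUAAGGACU"]), m6a)
        assert sorted(h.start for h in hits) == [0, 7]

    def test_degenerate_motif_rejected(self):
        flat = Motif("flat", np.full((6, 4), 0.25))
        with pytest.raises(ValueError, match="bits"):
            scan_motif_instances(_ds(["ACGUACGU"]), flat)

    def test_overlapping_matches_merged_keeping_best(self):
        motif = consensus_motif("aa", "AAAAA")
        hits = scan_motif_instances(_ds(["CCAAAAAACC"]), motif)
        assert len(hits) == 1


class TestScramble:
    def test_outside_window_untouched(self):
        inst = MotifInstance("s0", "m", 5, 10, 1.0)
        seq = "ACGUACGUACGUACGU"
        for out in scramble_instance(seq, inst, n_replicates=5, seed=0):
            assert len(out) == len(seq)
            assert out[:5] == seq[:5] and out[10:] == seq[10:]

    def test_window_base_frequencies_uniform(self):
        inst = MotifInstance("s0", "m", 0, 5, 1.0)
        reps = scramble_instance("GGGGG", inst, n_replicates=10_000, seed=1)
        counts = np.zeros(4)
        for r in reps:
            for c in r:
                counts["ACGU".index(c)] += 1
        freqs = counts / counts.sum()
        se = np.sqrt(0.25 * 0.75 / counts.sum())
        assert np.all(np.abs(freqs - 0.25) < 3 * se + 1e-9)

    def test_scrambled_window_rarely_retains_instance(self, rng):
        motif = consensus_motif("m", "GGACU")
        seq = "AACCGGACUAACC"
        inst = MotifInstance("s0", "m", 4, 9, 1.0)
        retained = 0
        for out in scramble_instance(seq, inst, n_replicates=400, seed=2):
            if any(s == 4 for s, _ in scan_sequence(out, motif)):
                retained += 1
        assert retained / 400 <= 0.05


class OracleModel:
    """Additive (optionally epistatic) ground-truth predictor over scanned motifs."""

    def __init__(self, effects, interaction=None, threshold=0.8):
        self.effects = effects  # list of (Motif, e)
        self.interaction = interaction  # (motif_a, motif_b, e_ab) or None
        self.threshold = threshold

    def predict_strings(self, seqs):
        out = []
        for s in seqs:
            present = {
                m.name
                for m, _e in self.effects
                if scan_sequence(s, m, self.threshold)
            }
            y = sum(e for m, e in self.effects if m.name in present)
            if self.interaction is not None:
                a, b, e_ab = self.interaction
                if a.name in present and b.name in present:
                    y += e_ab
            out.append(y)
        return np.array(out)


@pytest.fixture(scope="module")
def motifs_ab():
    return consensus_motif("A", "GGACUG"), consensus_motif("B", "CCGCAGC")


def _carrier_sequences(rng, n, a="GGACUG", b="CCGCAGC", length=50):
    seqs = []
    for _ in range(n):
        s = list(BASES[rng.integers(0, 4, length)])
        s[3 : 3 + len(a)] = a
        s[30 : 30 + len(b)] = b
        seqs.append("".join(s))
    return seqs


class TestQuadruples:
    def test_constant_model_gives_equal_quadruple(self):
        class Const:
            def predict_strings(self, seqs):
                return np.full(len(seqs), 7.0)

        ia = MotifInstance("s0", "A", 0, 5, 1.0)
        ib = MotifInstance("s0", "B", 10, 15, 1.0)
        q = mutagenesis_quadruple(Const(), "ACGUACGUACGUACGUACGU", ia, ib)
        assert q.o == q.a == q.b == q.n == 7.0

    def test_overlapping_instances_rejected(self):
        class Const:
            def predict_strings(self, seqs):
                return np.zeros(len(seqs))

        ia = MotifInstance("s0", "A", 0, 8, 1.0)
        ib = MotifInstance("s0", "B", 5, 12, 1.0)
        with pytest.raises(ValueError, match="overlap"):
            mutagenesis_quadruple(Const(), "ACGUACGUACGUACGU", ia, ib)

    def test_additive_oracle_has_no_epistatic_deviation(self, motifs_ab, rng):
        a, b = motifs_ab
        model = OracleModel([(a, 1.0), (b, 1.0)])
        seq = _carrier_sequences(rng, 1)[0]
        ia = MotifInstance("s0", "A", 3, 9, 1.0)
        ib = MotifInstance("s0", "B", 30, 37, 1.0)
        q = mutagenesis_quadruple(model, seq, ia, ib, n_replicates=16, seed=3)
        dev = (q.o - q.n) - ((q.a - q.n) + (q.b - q.n))
        assert abs(dev) < 0.2  # scramble noise only

    def test_epistatic_oracle_recovers_interaction_magnitude(self, motifs_ab, rng):
        a, b = motifs_ab
        model = OracleModel([(a, 1.0), (b, 1.0)], interaction=(a, b, 0.7))
        devs = []
        for i, seq in enumerate(_carrier_sequences(rng, 20)):
            ia = MotifInstance(f"s{i}", "A", 3, 9, 1.0)
            ib = MotifInstance(f"s{i}", "B", 30, 37, 1.0)
            q = mutagenesis_quadruple(model, seq, ia, ib, n_replicates=16, seed=i)
            devs.append((q.o - q.n) - ((q.a - q.n) + (q.b - q.n)))
        assert np.mean(devs) == pytest.approx(0.7, abs=0.1)


def exact_signed_rank_p(diffs):
    """Enumeration oracle: exact two-sided sign-flip distribution of W+."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = ranks[d > 0].sum()
    n = len(d)
    stats = []
    for signs in itertools.product([0, 1], repeat=n):
        stats.append(sum(r for r, s in zip(ranks, signs) if s))
    stats = np.array(stats)
    # two-sided: double the smaller tail
    lo = np.mean(stats <= w_obs)
    hi = np.mean(stats >= w_obs)
    return min(1.0, 2 * min(lo, hi))


class TestEpistasisTest:
    def test_zero_differences_are_none(self):
        quads = [MutagenesisQuadruple(f"s{i}", 2.0, 1.5, 1.5, 1.0) for i in range(12)]
        p, direction = epistasis_test(quads)
        assert direction == "none"

    def test_all_positive_differences_match_exact_enumeration(self, rng):
        devs = rng.uniform(0.5, 1.5, size=10)
        quads = [
            MutagenesisQuadruple(f"s{i}", 1.0 + d, 0.5, 0.5, 0.0) for i, d in enumerate(devs)
        ]
        p, direction = epistasis_test(quads)
        assert direction == "joint_greater"
        # exact one-sided p for 10 uniformly positive differences is 1/1024
        assert p == pytest.approx(2 / 1024, rel=1e-6)
        assert p == pytest.approx(exact_signed_rank_p(devs), rel=1e-6)

    def test_requires_ten_quadruples(self):
        quads = [MutagenesisQuadruple("s", 1, 0, 0, 0)] * 9
        with pytest.raises(ValueError, match="quadruples"):
            epistasis_test(quads)

    def test_null_rejection_rate_controlled(self, rng):
        n_rep, alpha = 1000, 0.05
        rejections = 0
        for _ in range(n_rep):
            devs = rng.normal(size=20)
            quads = [
                MutagenesisQuadruple(f"s{i}", d, 0.0, 0.0, 0.0) for i, d in enumerate(devs)
            ]
            _, direction = epistasis_test(quads, alpha=alpha)
            if direction != "none":
                rejections += 1
        se = np.sqrt(alpha * (1 - alpha) / n_rep)
        assert rejections / n_rep <= alpha + 2 * se


TRUTH_TABLE = {
    ("positive", "positive", "joint_greater"): "synergistic",
    ("positive", "positive", "joint_smaller"): "antagonistic",
    ("positive", "positive", "none"): "additive",
    ("negative", "negative", "joint_greater"): "antagonistic",
    ("negative", "negative", "joint_smaller"): "synergistic",
    ("negative", "negative", "none"): "additive",
}


class TestClassification:
    def test_same_sign_rules_match_hand_coded_table(self):
        for (sa, sb, direction), expected in TRUTH_TABLE.items():
            cls, both = classify_interaction(sa, sb, direction)
            assert cls == expected and not both

    @pytest.mark.parametrize(
        "dir_a, dir_b, expected, both",
        [
            ("joint_greater", "none", "sign", False),  # (o-n) > (a-n)
            ("none", "joint_smaller", "sign", False),  # (o-n) < (b-n)
            ("joint_greater", "joint_smaller", "sign", True),
            ("none", "none", "additive", False),
            ("joint_smaller", "joint_greater", "additive", False),
        ],
    )
    def test_mixed_sign_rules(self, dir_a, dir_b, expected, both):
        cls, flagged = classify_interaction(
            "positive", "negative", "none", direction_vs_a=dir_a, direction_vs_b=dir_b
        )
        assert cls == expected and flagged == both

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            classify_interaction("up", "positive", "none")
        with pytest.raises(ValueError):
            classify_interaction("positive", "negative", "none")  # missing mixed dirs


class TestAnalyzePair:
    def _dataset(self, rng, n=40):
        seqs = _carrier_sequences(rng, n)
        return LabeledSequenceSet(
            [SequenceRecord(f"s{i}", s, 0.0) for i, s in enumerate(seqs)]
        )

    def test_synergistic_oracle_classified_synergistic(self, motifs_ab, rng):
        a, b = motifs_ab
        model = OracleModel([(a, 1.0), (b, 1.0)], interaction=(a, b, 0.8))
        res = analyze_pair(model, self._dataset(rng), a, b, "positive", "positive", seed=1)
        assert res.interaction_class == "synergistic"
        assert res.median_deviation == pytest.approx(0.8, abs=0.15)

    def test_antagonistic_oracle_classified_antagonistic(self, motifs_ab, rng):
        a, b = motifs_ab
        model = OracleModel([(a, 1.0), (b, 1.0)], interaction=(a, b, -0.8))
        res = analyze_pair(model, self._dataset(rng), a, b, "positive", "positive", seed=2)
        assert res.interaction_class == "antagonistic"

    def test_inferred_signs_match_oracle_effects(self, motifs_ab, rng):
        a, b = motifs_ab
        model = OracleModel([(a, 1.0), (b, -1.0)])
        res = analyze_pair(model, self._dataset(rng), a, b, seed=3)
        assert {res.sign_a, res.sign_b} == {"positive", "negative"}
        # no interaction term: mixed signs with no directional dominance
        assert res.interaction_class in ("additive", "sign")

    def test_label_swap_symmetry(self, motifs_ab, rng):
        a, b = motifs_ab
        model = OracleModel([(a, 1.0), (b, 1.0)], interaction=(a, b, 0.8))
        ds = self._dataset(rng)
        r1 = analyze_pair(model, ds, a, b, "positive", "positive", seed=4)
        r2 = analyze_pair(model, ds, b, a, "positive", "positive", seed=4)
        assert r1.interaction_class == r2.interaction_class


class TestInteractionMap:
    def test_empty_results(self):
        mat, counts = interaction_map([])
        assert mat.empty and counts == {}

    def test_single_pair_is_mirrored_and_absence_distinct(self):
        from motifsyntax.interaction import EpistasisResult

        res = EpistasisResult("A", "B", "positive", "positive", 50, 0.01,
                              "joint_greater", "synergistic")
        mat, counts = interaction_map([res], motif_names=["A", "B", "C"])
        assert mat.loc["A", "B"] == "synergistic"
        assert mat.loc["B", "A"] == "synergistic"
        assert mat.loc["A", "C"] is np.nan or (isinstance(mat.loc["A", "C"], float))
        assert counts == {"synergistic": 1}

    def test_map_renders_to_file(self, tmp_path):
        from motifsyntax.interaction import EpistasisResult, plot_interaction_map

        res = EpistasisResult("A", "B", "positive", "positive", 50, 0.01,
                              "joint_greater", "synergistic")
        out = tmp_path / "map.png"
        plot_interaction_map([res], str(out))
        assert out.exists() and out.stat().st_size > 0

    def test_tallies_match_result_list(self):
        from motifsyntax.interaction import EpistasisResult

        classes = ["synergistic", "synergistic", "antagonistic", "additive"]
        results = [
            EpistasisResult(f"M{i}", f"N{i}", "positive", "positive", 20, 0.01,
                            "joint_greater", c)
            for i, c in enumerate(classes)
        ]
        _, counts = interaction_map(results)
        assert counts == {"synergistic": 2, "antagonistic": 1, "additive": 1}
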
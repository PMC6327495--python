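import edlib
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sshapelet import (
    Alphabet,
    SequenceShapeletTransform,
    SymbolicDataset,
    discretize_dataset,
    entropy,
    generate,
    optimal_split,
    partition_gain,
    sample_candidates,
    select_shapelet,
    subsequence_distance,
)
from sshapelet.synthetic import SyntheticConfig, motif_recovery_config
from conftest import random_symbolic_column
from oracles import brute_subsequence_distance, exhaustive_optimal_split

seqs = st.text(alphabet="abcde", min_size=1, max_size=8)


class TestEntropy:
    @pytest.mark.parametrize("labels,expected", [
        (["p"] * 1 + ["n"] * 2, 0.918),   # one-third / two-thirds split
        (["p"] * 3 + ["n"] * 7, 0.881),   # 3:7 split
        (["p"] * 4, 0.0),
        (["p", "n"], 1.0),
    ])
    def test_known_values(self, labels, expected):
        assert entropy(labels) == pytest.approx(expected, abs=5e-4)

    def test_empty_multiset_rejected(self):
        with pytest.raises(ValueError):
            entropy([])


class TestPartitionGain:
    def test_trivial_split_gains_nothing(self):
        parent = ["p", "p", "n"]
        assert partition_gain(parent, [parent, []]) == pytest.approx(0.0)

    def test_pure_split_of_balanced_parent_gains_one_bit(self):
        parent = ["p", "p", "n", "n"]
        assert partition_gain(parent, [["p", "p"], ["n", "n"]]) == pytest.approx(1.0)

    def test_worked_binary_split(self):
        # 4 pos / 8 neg split into {4 pos, 2 neg} and {6 neg}
        parent = ["p"] * 4 + ["n"] * 8
        parts = [["p"] * 4 + ["n"] * 2, ["n"] * 6]
        assert partition_gain(parent, parts) == pytest.approx(0.459, abs=5e-4)

    def test_non_partition_rejected(self):
        with pytest.raises(ValueError):
            partition_gain(["p", "n"], [["p"], ["p"]])


class TestSubsequenceDistance:
    def test_identity_and_exact_substring(self):
        assert subsequence_distance("abba", "abba") == 0
        assert subsequence_distance("ab", "cabd") == 0

    def test_empty_target_uses_strategy_value(self):
        assert subsequence_distance("abba", "", empty_distance=4) == 4
        with pytest.raises(ValueError):
            subsequence_distance("abba", "")

    @given(s=seqs, target=seqs)
    @settings(max_examples=300, derandomize=True, deadline=None)
    def test_matches_bruteforce_and_bounded_by_length(self, s, target):
        d = subsequence_distance(s, target)
        assert d == brute_subsequence_distance(s, target)
        assert 0 <= d <= len(s)

    @given(s=seqs, target=seqs)
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_window_distances_match_edlib(self, s, target):
        # independent cross-check of the inner equal-length edit distance
        if len(target) >= len(s):
            expected = min(
                edlib.align(s, target[i:i + len(s)], mode="NW")["editDistance"]
                for i in range(len(target) - len(s) + 1)
            )
        else:
            expected = edlib.align(s, target, mode="NW")["editDistance"]
        assert subsequence_distance(s, target) == expected


class TestSampleCandidates:
    @staticmethod
    def _symbolic(records, labels=None):
        labels = labels or {o: "x" for o, _ in records}
        return SymbolicDataset(
            feature_ids=["f"], object_ids=[o for o, _ in records],
            records={(o, "f"): t for o, t in records}, labels=labels,
            alphabet_size=3,
        )

    def test_small_space_is_enumerated(self):
        symb = self._symbolic([("o1", "abc")])
        cands = sample_candidates(symb, "f", 1000, rng=0)
        assert sorted({c.sequence for c in cands}) == \
            ["a", "ab", "abc", "b", "bc", "c"]
        assert len(cands) == 6

    def test_candidates_are_observed_substrings(self):
        symb = self._symbolic([("o1", "abcab"), ("o2", "bca"), ("o3", "")])
        for c in sample_candidates(symb, "f", 100, rng=3):
            assert c.sequence in symb.record(c.object_id, "f")

    def test_deterministic_under_seed(self):
        symb = self._symbolic([("o1", "abcabcab"), ("o2", "bcaacb")])
        a = sample_candidates(symb, "f", 30, rng=11)
        b = sample_candidates(symb, "f", 30, rng=11)
        assert a == b

    def test_length_distribution_uniform(self):
        # enough records that 10k draws stay below the position-space size,
        # exercising the random-draw path: lengths in [1, l_max=3] uniform
        from scipy.stats import chisquare
        symb = self._symbolic([(f"o{i}", "abc") for i in range(2000)])
        cands = sample_candidates(symb, "f", 10_000, rng=5)
        lengths = np.array([len(c.sequence) for c in cands])
        counts = np.bincount(lengths, minlength=4)[1:]
        assert counts.sum() == 10_000
        assert chisquare(counts).pvalue > 1e-3

    def test_all_empty_feature_rejected(self):
        symb = self._symbolic([("o1", ""), ("o2", "")])
        with pytest.raises(ValueError):
            sample_candidates(symb, "f", 10, rng=0)


class TestOptimalSplit:
    def test_perfectly_separable_column(self):
        # distances pos=[0,0,1], neg=[4,5,5] -> full parent entropy recovered
        column = [("aaa", "p"), ("aaab", "p"), ("aaba", "p"),
                  ("bbbb", "n"), ("bbbbb", "n"), ("bbcbb", "n")]
        for strategy in ("plain", "mc", "lr"):
            ev = optimal_split("aaa", column, strategy)
            assert ev.gain == pytest.approx(entropy([y for _, y in column]))
            assert 1 <= ev.threshold <= 3

    def test_mc_ignores_empty_records(self):
        base = [("aa", "p"), ("bb", "n")]
        with_empty = base + [("", "p"), ("", "n"), ("", "n")]
        assert optimal_split("aa", with_empty, "mc") == \
            optimal_split("aa", base, "mc")

    @pytest.mark.parametrize("strategy", ["plain", "mc", "lr"])
    def test_matches_exhaustive_search(self, strategy):
        rng = np.random.default_rng(42)
        for _ in range(150):
            s, column = random_symbolic_column(rng)
            ev = optimal_split(s, column, strategy)
            delta, gain, side, empty_d = exhaustive_optimal_split(s, column, strategy)
            assert ev.threshold == delta
            assert ev.gain == pytest.approx(gain, abs=1e-9)
            assert ev.empty_distance == pytest.approx(empty_d)

    def test_lr_never_below_plain(self):
        rng = np.random.default_rng(43)
        for _ in range(200):
            s, column = random_symbolic_column(rng, require_empty=True)
            g_lr = optimal_split(s, column, "lr").gain
            g_plain = optimal_split(s, column, "plain").gain
            assert g_lr >= g_plain - 1e-9

    def test_gain_bounded_by_parent_entropy(self):
        rng = np.random.default_rng(44)
        for _ in range(100):
            s, column = random_symbolic_column(rng)
            for strategy in ("plain", "lr"):
                ev = optimal_split(s, column, strategy)
                assert -1e-12 <= ev.gain <= entropy([y for _, y in column]) + 1e-12

    def test_all_empty_rejected(self):
        with pytest.raises(ValueError):
            optimal_split("a", [("", "p"), ("", "n")], "mc")


class TestSelectShapelet:
    @staticmethod
    def _symbolic(alpha, records, labels):
        return SymbolicDataset(
            feature_ids=["f"], object_ids=list(labels),
            records={(o, "f"): t for o, t in records.items()},
            labels=labels, alphabet_size=alpha,
        )

    def test_single_candidate_selected(self):
        from sshapelet import Candidate
        labels = {"o1": "p", "o2": "n"}
        symb = self._symbolic(2, {"o1": "ab", "o2": "ba"}, labels)
        cand = Candidate("ab", 2, "f", "o1", 0)
        sh = select_shapelet({2: symb}, "f", {2: [cand]}, "plain")
        assert sh.sequence == "ab" and sh.alphabet_size == 2

    def test_gain_tie_prefers_smaller_alphabet(self):
        from sshapelet import Candidate
        labels = {"o1": "p", "o2": "n"}
        records = {"o1": "ab", "o2": "bb"}
        by_alpha = {a: self._symbolic(a, records, labels) for a in (2, 3)}
        cands = {a: [Candidate("ab", a, "f", "o1", 0)] for a in (2, 3)}
        sh = select_shapelet(by_alpha, "f", cands, "plain")
        assert sh.alphabet_size == 2

    def test_planted_motif_outranks_noise_features(self):
        # informative features' shapelets get strictly higher gain (median)
        gaps = []
        for seed in range(5):
            config = motif_recovery_config(seed, n_objects=80)
            est = SequenceShapeletTransform(
                strategy="plain", n_candidates=100, random_state=seed
            ).fit(generate(config))
            by_feat = {sh.feature_id: sh.gain for sh in est.shapelets_}
            motif_gain = by_feat["F00_motif"]
            noise_gain = max(g for f, g in by_feat.items() if "noise" in f)
            gaps.append(motif_gain - noise_gain)
        assert np.median(gaps) > 0


class TestDiscoverAll:
    def test_one_shapelet_per_retained_feature_and_determinism(self):
        ds = generate(SyntheticConfig(n_objects=60, seed=3))
        est1 = SequenceShapeletTransform(strategy="lr", random_state=9).fit(ds)
        est2 = SequenceShapeletTransform(strategy="lr", random_state=9).fit(ds)
        assert len(est1.shapelets_) == len(est1.feature_ids_)
        assert est1.shapelets_ == est2.shapelets_
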
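import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pranktgx as px
from conftest import dice_bruteforce, random_signature


def _topk_sig(cid, up, down):
    return px.Signature(cid, frozenset(up), frozenset(down), mode="topk")


def _thr_sig(cid, up, down):
    return px.Signature(cid, frozenset(up), frozenset(down), mode="threshold")


class TestDice:
    def test_self_similarity_is_one(self):
        sig = _topk_sig("a", {"g1", "g2"}, {"g3", "g4"})
        assert px.dice(sig, sig) == 1.0

    def test_disjoint_signatures_score_zero(self):
        a = _topk_sig("a", {"g1"}, {"g2"})
        b = _topk_sig("b", {"g3"}, {"g4"})
        assert px.dice(a, b) == 0.0

    def test_k200_partial_overlap_matches_fixed_denominator(self):
        # 50 shared up + 30 shared down out of 400+400 genes -> 0.2
        up_a = {f"u{i}" for i in range(200)}
        down_a = {f"d{i}" for i in range(200)}
        up_b = {f"u{i}" for i in range(50)} | {f"U{i}" for i in range(150)}
        down_b = {f"d{i}" for i in range(30)} | {f"D{i}" for i in range(170)}
        a = _topk_sig("a", up_a, down_a)
        b = _topk_sig("b", up_b, down_b)
        assert px.dice(a, b) == pytest.approx(0.2)

    def test_direction_flip_scores_zero(self):
        a = _topk_sig("a", {"g1", "g2"}, {"g3", "g4"})
        b = _topk_sig("b", {"g3", "g4"}, {"g1", "g2"})
        assert px.dice(a, b) == 0.0

    def test_mixed_k_rejected(self):
        a = _topk_sig("a", {"g1"}, {"g2"})
        b = _topk_sig("b", {"g3", "g4"}, {"g5", "g6"})
        with pytest.raises(ValueError, match="k="):
            px.dice(a, b)

    def test_threshold_mode_generalized_denominator(self):
        a = _thr_sig("a", {"g1", "g2", "g3"}, {"g4"})
        b = _thr_sig("b", {"g1"}, {"g4", "g5"})
        # shared = 1 up + 1 down; sizes 4 + 3
        assert px.dice(a, b) == pytest.approx(2 * 2 / 7)

    def test_both_empty_threshold_signatures_score_zero(self):
        a = _thr_sig("a", set(), set())
        b = _thr_sig("b", set(), set())
        assert px.dice(a, b) == 0.0

    def test_fixed_denominator_override(self):
        a = _thr_sig("a", {"g1", "g2"}, set())
        b = _thr_sig("b", {"g1", "g2"}, set())
        # 2(N_up + N_down) / 800 with 2 shared up genes
        assert px.dice(a, b, fixed_denominator=800) == pytest.approx(4 / 800)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_dice_is_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        universe = np.array([f"g{i}" for i in range(60)])
        a = random_signature(rng, universe, 10)
        b = random_signature(rng, universe, 10)
        assert px.dice(a, b) == px.dice(b, a)

    def test_identical_partition_of_2k_universe(self):
        universe = [f"g{i}" for i in range(20)]
        a = _topk_sig("a", universe[:10], universe[10:])
        b = _topk_sig("b", universe[:10], universe[10:])
        assert px.dice(a, b) == 1.0
        flipped = _topk_sig("b", universe[10:], universe[:10])
        assert px.dice(a, flipped) == 0.0


class TestPairwiseSimilarity:
    def test_matches_bruteforce_oracle_exactly(self):
        rng = np.random.default_rng(123)
        universe = np.array([f"g{i}" for i in range(300)])
        sigs = [random_signature(rng, universe, 40) for _ in range(20)]
        sim = px.pairwise_similarity(sigs, "sys")
        for i in range(20):
            for j in range(20):
                expected = 1.0 if i == j else dice_bruteforce(sigs[i], sigs[j])
                assert sim.values[i, j] == expected

    def test_threshold_signatures_match_oracle(self):
        rng = np.random.default_rng(7)
        universe = np.array([f"g{i}" for i in range(100)])
        sigs = []
        for i in range(10):
            n_up, n_down = rng.integers(0, 10, size=2)
            picked = rng.choice(universe, size=n_up + n_down, replace=False)
            sigs.append(
                _thr_sig(f"c{i}", set(picked[:n_up]), set(picked[n_up:]))
            )
        sim = px.pairwise_similarity(sigs, "sys")
        for i in range(10):
            for j in range(i + 1, 10):
                assert sim.values[i, j] == pytest.approx(
                    dice_bruteforce(sigs[i], sigs[j]), abs=1e-15
                )

    def test_identical_signatures_give_offdiagonal_one(self):
        a = _topk_sig("a", {"g1"}, {"g2"})
        b = _topk_sig("b", {"g1"}, {"g2"})
        sim = px.pairwise_similarity([a, b], "sys")
        assert sim.values[0, 1] == 1.0

    def test_mutually_disjoint_signatures_give_zero(self):
        sigs = [
            _topk_sig("a", {"g1"}, {"g2"}),
            _topk_sig("b", {"g3"}, {"g4"}),
            _topk_sig("c", {"g5"}, {"g6"}),
        ]
        sim = px.pairwise_similarity(sigs, "sys")
        off = sim.offdiagonal()
        assert (off == 0).all()

    def test_duplicate_compound_ids_rejected(self):
        a = _topk_sig("a", {"g1"}, {"g2"})
        with pytest.raises(ValueError, match="duplicate"):
            px.pairwise_similarity([a, a], "sys")

    def test_square_tsv_round_trip(self, tmp_path):
        rng = np.random.default_rng(9)
        universe = np.array([f"g{i}" for i in range(80)])
        sigs = [random_signature(rng, universe, 10) for _ in range(5)]
        sim = px.pairwise_similarity(sigs, "sys")
        path = tmp_path / "sim.tsv"
        sim.write_square(path)
        from pranktgx.similarity import read_similarity_matrix

        back = read_similarity_matrix(path, "sys")
        assert back.compound_ids == sim.compound_ids
        np.testing.assert_array_equal(back.values, sim.values)


class TestMeanSimilarity:
    def test_constant_offdiagonal(self):
        values = np.full((4, 4), 0.3)
        np.fill_diagonal(values, 1.0)
        sim = px.SimilarityMatrix("s", ["a", "b", "c", "d"], values)
        assert px.mean_similarity(sim) == pytest.approx(0.3)

    def test_three_compound_mean(self):
        values = np.array([[1.0, 0.1, 0.2], [0.1, 1.0, 0.3], [0.2, 0.3, 1.0]])
        sim = px.SimilarityMatrix("s", ["a", "b", "c"], values)
        assert px.mean_similarity(sim) == pytest.approx(0.2)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(21)
        n = 12
        raw = rng.uniform(0, 1, size=(n, n))
        values = (raw + raw.T) / 2
        np.fill_diagonal(values, 1.0)
        sim = px.SimilarityMatrix("s", [f"c{i}" for i in range(n)], values)
        expected = np.mean(
            [values[i, j] for i in range(n) for j in range(i + 1, n)]
        )
        assert px.mean_similarity(sim) == pytest.approx(expected, abs=1e-15)

    def test_single_compound_rejected(self):
        sim = px.SimilarityMatrix("s", ["a"], np.array([[1.0]]))
        with pytest.raises(ValueError, match="two compounds"):
            px.mean_similarity(sim)


class TestChemTgxCorrelation:
    def _sim(self, values):
        n = values.shape[0]
        return px.SimilarityMatrix("s", [f"c{i}" for i in range(n)], values)

    def _mat(self, pair_values, n):
        values = np.zeros((n, n))
        np.fill_diagonal(values, 1.0)
        for (i, j), v in pair_values.items():
            values[i, j] = values[j, i] = v
        return self._sim(values)

    def test_equal_values_give_perfect_correlation(self):
        tgx = self._mat({(0, 1): 0.3, (0, 2): 0.5, (1, 2): 0.7}, 3)
        chem = px.ChemicalSimilarityTable(
            {frozenset(p): v for p, v in
             [(("c0", "c1"), 0.3), (("c0", "c2"), 0.5), (("c1", "c2"), 0.7)]}
        )
        r, n = px.chem_tgx_correlation(tgx, chem, chem_cutoff=0.2)
        assert r == pytest.approx(1.0)
        assert n == 3

    def test_reversed_values_give_negative_correlation(self):
        tgx = self._mat({(0, 1): 0.7, (0, 2): 0.5, (1, 2): 0.3}, 3)
        chem = px.ChemicalSimilarityTable(
            {frozenset(p): v for p, v in
             [(("c0", "c1"), 0.3), (("c0", "c2"), 0.5), (("c1", "c2"), 0.7)]}
        )
        r, _ = px.chem_tgx_correlation(tgx, chem, chem_cutoff=0.2)
        assert r == pytest.approx(-1.0)

    def test_cutoff_filters_pairs(self):
        pair_chems = {
            ("c0", "c1"): 0.1, ("c0", "c2"): 0.15, ("c0", "c3"): 0.3,
            ("c1", "c2"): 0.4, ("c1", "c3"): 0.5,
        }
        tgx = self._mat(
            {(0, 1): 0.2, (0, 2): 0.3, (0, 3): 0.25, (1, 2): 0.9, (1, 3): 0.1},
            4,
        )
        chem = px.ChemicalSimilarityTable(
            {frozenset(p): v for p, v in pair_chems.items()}
        )
        _, n = px.chem_tgx_correlation(tgx, chem, chem_cutoff=0.2)
        assert n == 3

    def test_too_few_surviving_pairs_rejected(self):
        tgx = self._mat({(0, 1): 0.2}, 2)
        chem = px.ChemicalSimilarityTable({frozenset(("c0", "c1")): 0.9})
        with pytest.raises(ValueError, match="at least 3"):
            px.chem_tgx_correlation(tgx, chem)
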
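import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pranktgx as px
from conftest import auc_bruteforce


def _pairs(n):
    return [frozenset((f"c{i}", f"c{j}")) for i, j in
            itertools.combinations(range(n), 2)]


def _sim(values, system="s"):
    n = values.shape[0]
    return px.SimilarityMatrix(system, [f"c{i}" for i in range(n)], values)


def _random_sim(rng, n, system="s"):
    raw = rng.uniform(0, 1, size=(n, n))
    values = (raw + raw.T) / 2
    np.fill_diagonal(values, 1.0)
    return _sim(values, system)


class TestBinarize:
    def test_strict_inequality_at_cutoff(self):
        values = np.array(
            [[1.0, 0.41, 0.40], [0.41, 1.0, 0.39], [0.40, 0.39, 1.0]]
        )
        labels = px.binarize(_sim(values), cutoff=0.4)
        assert labels[frozenset(("c0", "c1"))] == 1
        assert labels[frozenset(("c0", "c2"))] == 0
        assert labels[frozenset(("c1", "c2"))] == 0

    def test_all_zero_matrix_gives_all_negative(self):
        values = np.zeros((3, 3))
        np.fill_diagonal(values, 1.0)
        assert set(px.binarize(_sim(values)).values()) == {0}

    def test_quantile_mode_uses_own_distribution(self):
        rng = np.random.default_rng(2)
        sim = _random_sim(rng, 30)
        labels = px.binarize(sim, quantile=0.95)
        off = sim.offdiagonal()
        cut = np.quantile(off, 0.95)
        assert sum(labels.values()) == int((off > cut).sum())
        # roughly the top 5% of pairs are positive
        assert 0 < sum(labels.values()) <= np.ceil(0.06 * off.size)


class TestRocAuc:
    def test_perfect_separation(self):
        keys = _pairs(4)[:4]
        labels = dict(zip(keys, [1, 1, 0, 0]))
        scores = dict(zip(keys, [0.9, 0.8, 0.2, 0.1]))
        assert px.roc_auc(labels, scores) == 1.0

    def test_perfect_inversion(self):
        keys = _pairs(3)[:2]
        labels = dict(zip(keys, [1, 0]))
        scores = dict(zip(keys, [0.2, 0.8]))
        assert px.roc_auc(labels, scores) == 0.0

    def test_three_of_four_comparisons_won(self):
        keys = _pairs(4)[:4]
        labels = dict(zip(keys, [1, 1, 0, 0]))
        scores = dict(zip(keys, [0.3, 0.2, 0.25, 0.1]))
        assert px.roc_auc(labels, scores) == 0.75

    def test_all_tied_scores_give_half(self):
        keys = _pairs(4)[:4]
        labels = dict(zip(keys, [1, 1, 0, 0]))
        scores = dict(zip(keys, [0.5] * 4))
        assert px.roc_auc(labels, scores) == 0.5

    @pytest.mark.parametrize("label_value, missing", [(1, "negative"),
                                                      (0, "positive")])
    def test_single_class_error_names_missing_class(self, label_value, missing):
        keys = _pairs(3)[:3]
        labels = dict(zip(keys, [label_value] * 3))
        scores = dict(zip(keys, [0.1, 0.2, 0.3]))
        with pytest.raises(ValueError, match=missing):
            px.roc_auc(labels, scores)

    def test_mismatched_keys_rejected(self):
        keys = _pairs(4)
        labels = {keys[0]: 1, keys[1]: 0}
        scores = {keys[0]: 0.5, keys[2]: 0.5}
        with pytest.raises(ValueError, match="differ"):
            px.roc_auc(labels, scores)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_bruteforce_on_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 51))
        keys = [frozenset((f"a{i}", f"b{i}")) for i in range(n)]
        labels = dict(zip(keys, rng.integers(0, 2, size=n)))
        if sum(labels.values()) in (0, n):
            labels[keys[0]] = 1 - labels[keys[0]]
        # discretized scores so ties occur
        scores = dict(zip(keys, np.round(rng.uniform(size=n), 1)))
        assert px.roc_auc(labels, scores) == pytest.approx(
            auc_bruteforce(labels, scores), abs=1e-12
        )

    def test_agrees_with_sklearn_reference(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(17)
        n = 200
        keys = [frozenset((f"a{i}", f"b{i}")) for i in range(n)]
        y = rng.integers(0, 2, size=n)
        y[0], y[1] = 0, 1
        s = np.round(rng.normal(size=n), 1)
        labels = dict(zip(keys, y))
        scores = dict(zip(keys, s))
        assert px.roc_auc(labels, scores) == pytest.approx(
            roc_auc_score(y, s), abs=1e-12
        )


class TestPRankScore:
    def test_self_concordance_is_one(self, default_sims):
        sim = default_sims["InVitro"]
        sim_copy = px.SimilarityMatrix("copy", sim.compound_ids, sim.values)
        res = px.prank_score(sim, sim_copy, cutoff=0.4)
        assert 0 < res.n_positive_a < res.n_pairs
        assert res.prank_score == 1.0
        assert not res.partial

    def test_symmetric_under_argument_swap(self):
        rng = np.random.default_rng(31)
        a = _random_sim(rng, 20, "A")
        b = _random_sim(rng, 20, "B")
        r1 = px.prank_score(a, b, quantile=0.9)
        r2 = px.prank_score(b, a, quantile=0.9)
        assert r1.prank_score == r2.prank_score
        assert r1.auc_a_labels == r2.auc_b_labels

    def test_invariant_to_monotone_transform_of_scores(self):
        rng = np.random.default_rng(32)
        a = _random_sim(rng, 15, "A")
        b = _random_sim(rng, 15, "B")
        b_sq = px.SimilarityMatrix("B", b.compound_ids, b.values**2)
        r = px.prank_score(a, b, quantile=0.9)
        r_sq = px.prank_score(a, b_sq, quantile=0.9)
        assert r.auc_a_labels == pytest.approx(r_sq.auc_a_labels, abs=1e-12)

    def test_compound_sets_intersected(self):
        rng = np.random.default_rng(33)
        a = _random_sim(rng, 12, "A")
        big = _random_sim(rng, 15, "B")
        res = px.prank_score(a, big, quantile=0.9)
        assert res.n_pairs == 12 * 11 // 2

    def test_single_class_direction_flagged_partial(self):
        rng = np.random.default_rng(34)
        a = _random_sim(rng, 10, "A")
        low = px.SimilarityMatrix(
            "B", a.compound_ids, np.full((10, 10), 0.0) + np.eye(10)
        )
        res = px.prank_score(a, low, cutoff=0.4)
        assert res.partial
        assert res.auc_b_labels is None

    def test_permutation_null_centers_at_half(self, default_sims):
        sim = default_sims["InVitro"]
        labels = px.binarize(sim, quantile=0.95)
        keys = list(labels)
        y = np.array([labels[k] for k in keys])
        values = np.array([sim.pair_values()[k] for k in keys])
        rng = np.random.default_rng(0)
        from pranktgx.prank import _auc_from_arrays

        aucs = [
            _auc_from_arrays(y, rng.permutation(values)) for _ in range(300)
        ]
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.02)


class TestGeneSetPRank:
    def test_planted_pathway_concordant_across_systems(self, default_bundle):
        bundle = default_bundle
        systems = list(bundle.matrices.values())
        planted_ids = list(bundle.ground_truth["planted_pathways"])
        sets = {
            pid: bundle.gene_sets.sets[pid]
            for pid in planted_ids[:1] + ["PW_DECOY_00"]
        }
        collection = px.GeneSetCollection(sets, bundle.gene_sets.min_size)
        results = px.prank_by_geneset(
            systems, collection, fc_threshold=1.5, quantile=0.9
        )
        assert set(pid for pid, _ in results) <= set(sets)
        planted_scores = [
            res.prank_score
            for (pid, _), res in results.items()
            if pid == planted_ids[0] and res.prank_score is not None
        ]
        assert planted_scores and min(planted_scores) > 0.5

    def test_top_pathway_overlap_regions_partition_lists(self, default_bundle):
        bundle = default_bundle
        results = px.prank_by_geneset(
            list(bundle.matrices.values()), bundle.gene_sets, quantile=0.9
        )
        top_n = 5
        tops = px.top_pathways(results, top_n=top_n)
        regions = px.top_pathway_overlap(results, top_n=top_n)
        for pair, top in tops.items():
            members = set().union(
                *(r for combo, r in regions.items() if pair in combo)
            )
            assert members == set(top)


class TestConditionSweep:
    def test_condition_by_pair_cardinality(self):
        rng = np.random.default_rng(35)
        sims = {s: _random_sim(rng, 10, s) for s in ("A", "B", "C")}
        grids = {
            (dose, time): sims
            for dose in ("low", "mid", "high")
            for time in ("3h", "6h", "9h", "24h")
        }
        table = px.condition_sweep(grids, quantile=0.9)
        assert len(table) == 36
        assert set(table["dose"]) == {"low", "mid", "high"}

    def test_identical_matrices_score_one(self):
        rng = np.random.default_rng(36)
        base = _random_sim(rng, 12, "A")
        twin = px.SimilarityMatrix("B", base.compound_ids, base.values)
        table = px.condition_sweep({("high", "24h"): {"A": base, "B": twin}},
                                   quantile=0.9)
        assert table["prank_score"].tolist() == [1.0]

    def test_prank_tracks_dose_dependent_signal_sharing(self):
        # shared-signal fraction rising with dose should raise PRank; check
        # the low-vs-high contrast over seeded replicates
        from pranktgx.simulate import SyntheticConfig, generate

        def sims_at(rho, seed):
            cfg = SyntheticConfig(
                n_genes=1000, n_compounds=24,
                rho=(("InVivo_S", "InVivo_R", rho),
                     ("InVitro", "InVivo_R", rho),
                     ("InVitro", "InVivo_S", rho)),
                categories=(), planted_pathways=(), n_decoy_pathways=0,
                seed=seed,
            )
            bundle = generate(cfg)
            return {
                s: px.pairwise_similarity(px.make_signatures(m, k=80), s)
                for s, m in bundle.matrices.items()
            }

        wins = 0
        for seed in range(10):
            grids = {
                (dose, "24h"): sims_at(rho, seed + 100 * i)
                for i, (dose, rho) in enumerate(
                    [("low", 0.2), ("mid", 0.5), ("high", 0.8)]
                )
            }
            table = px.condition_sweep(grids, quantile=0.95)
            by_dose = table.groupby("dose")["prank_score"].mean()
            wins += by_dose["high"] > by_dose["low"]
        assert wins >= 8

    def test_single_system_condition_rejected(self):
        rng = np.random.default_rng(37)
        with pytest.raises(ValueError, match="need at least 2"):
            px.condition_sweep({("high", "24h"): {"A": _random_sim(rng, 5)}})
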
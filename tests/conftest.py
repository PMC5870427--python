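import itertools

import numpy as np
import pandas as pd
import pytest

import pranktgx as px
from pranktgx.simulate import SyntheticConfig, generate

N_RECOVERY_SEEDS = 20


@pytest.fixture(scope="session")
def triad_runs():
    """Default-condition synthetic triads over the recovery seeds.

    Each entry is ``(bundle, {system: SimilarityMatrix})`` with top-200
    signatures; shared by the ordering-, stability- and pathway-recovery
    tests so each bundle is generated once.
    """
    runs = []
    for seed in range(N_RECOVERY_SEEDS):
        bundle = generate(SyntheticConfig(seed=seed))
        sims = {
            system: px.pairwise_similarity(
                px.make_signatures(matrix, k=200), system
            )
            for system, matrix in bundle.matrices.items()
        }
        runs.append((bundle, sims))
    return runs


@pytest.fixture(scope="session")
def default_bundle(triad_runs):
    return triad_runs[0][0]


@pytest.fixture(scope="session")
def default_sims(triad_runs):
    return triad_runs[0][1]


@pytest.fixture
def tiny_matrix():
    """6 genes x 3 compounds with hand-picked log2 fold changes."""
    data = pd.DataFrame(
        {
            "drugA": [2.0, 1.0, 0.1, -0.2, -1.0, -2.5],
            "drugB": [-2.5, -1.0, -0.2, 0.1, 1.0, 2.0],
            "drugC": [2.0, 1.0, 0.1, -0.2, -1.0, -2.5],
        },
        index=[f"g{i}" for i in range(1, 7)],
    )
    return px.FoldChangeMatrix("tiny", ("high", "24h"), data)


def random_signature(rng, universe, k):
    """A random top-k signature over ``universe`` (helper for oracles)."""
    picked = rng.choice(universe, size=2 * k, replace=False)
    return px.Signature(
        compound_id=f"c{rng.integers(1 << 30)}",
        up=frozenset(picked[:k]),
        down=frozenset(picked[k:]),
        mode="topk",
    )


def dice_bruteforce(sig_a, sig_b):
    """Independent Dice oracle: explicit set intersections and sizes."""
    shared = len(set(sig_a.up) & set(sig_b.up)) + len(
        set(sig_a.down) & set(sig_b.down)
    )
    if sig_a.mode == "topk" and sig_b.mode == "topk":
        return shared / (2 * len(sig_a.up))
    total = len(sig_a.up) + len(sig_a.down) + len(sig_b.up) + len(sig_b.down)
    return 0.0 if total == 0 else 2 * shared / total


def auc_bruteforce(labels, scores):
    """AUC oracle: enumerate all positive-negative comparisons, ties = 1/2."""
    pos = [scores[k] for k in labels if labels[k] == 1]
    neg = [scores[k] for k in labels if labels[k] == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def bh_bruteforce(pvals):
    """BH step-up oracle straight from the definition."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        value = min(1.0, pvals[i] * m / (rank_idx + 1))
        running = min(running, value)
        adjusted[i] = running
    return adjusted


def all_pair_prank_scores(sims, cutoff=None, quantile=0.95):
    """PRank for every system pair of one synthetic run."""
    out = {}
    for sa, sb in itertools.combinations(sims, 2):
        kwargs = {"quantile": quantile} if cutoff is None else {"cutoff": cutoff}
        out[frozenset((sa, sb))] = px.prank_score(sims[sa], sims[sb], **kwargs)
    return out
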
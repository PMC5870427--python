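"""Pair-ranking (PRank) concordance between assay systems.

The PRank score asks: if compound pairs that look similar in one assay system
(Dice above a cutoff) are taken as the "positive" pairs, how well do the other
system's pairwise similarities rank those positives above the rest?  That
ranking quality is the ROC-AUC, computed by the Mann-Whitney rank formulation
(tied scores contribute 1/2 per tied positive-negative comparison).

Which system supplies labels and which supplies scores is arbitrary, so both
directions are computed and their mean is reported as the (symmetric) PRank
score; the per-direction AUCs are always retained.

The default cutoff is Dice > 0.4 (strict).  A quantile mode is also provided
— binarizing at e.g. the 95th percentile of a system's own off-diagonal
values — since a fixed cutoff chosen for one similarity distribution may sit
above or below all values of another.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import FoldChangeMatrix, GeneSetCollection
from .signatures import make_geneset_signature
from .similarity import SimilarityMatrix, pairwise_similarity

logger = logging.getLogger(__name__)

Pair = frozenset


@dataclass
class PRankResult:
    """Concordance of two assay systems.

    ``auc_a_labels`` uses the first system's binarized pairs as labels scored
    by the second system's similarities; ``auc_b_labels`` is the reverse.
    ``prank_score`` is their mean and is invariant under swapping the two
    systems.  A direction whose binarization produces a single class has an
    undefined AUC (``None``); the result is then flagged ``partial`` and
    ``prank_score`` is the remaining defined AUC.
    """

    system_pair: tuple[str, str]
    cutoff_a: float
    cutoff_b: float
    auc_a_labels: float | None
    auc_b_labels: float | None
    prank_score: float | None
    n_pairs: int
    n_positive_a: int
    n_positive_b: int
    partial: bool = False

    def to_dict(self) -> dict:
        return {
            "system_a": self.system_pair[0],
            "system_b": self.system_pair[1],
            "cutoff_a": self.cutoff_a,
            "cutoff_b": self.cutoff_b,
            "auc_a_labels": self.auc_a_labels,
            "auc_b_labels": self.auc_b_labels,
            "prank_score": self.prank_score,
            "n_pairs": self.n_pairs,
            "n_positive_a": self.n_positive_a,
            "n_positive_b": self.n_positive_b,
            "partial": self.partial,
        }


def binarize(
    matrix: SimilarityMatrix,
    cutoff: float = 0.4,
    quantile: float | None = None,
) -> dict[Pair, int]:
    """Binarize off-diagonal similarities: pair -> 1 iff Dice > cutoff.

    The inequality is strict.  If ``quantile`` is given (e.g. 0.95), the
    cutoff is that quantile of the matrix's own off-diagonal values and the
    ``cutoff`` argument is ignored.
    """
    if quantile is not None:
        if not 0 < quantile < 1:
            raise ValueError("quantile must be in (0, 1)")
        cutoff = float(np.quantile(matrix.offdiagonal(), quantile))
    return {
        pair: int(value > cutoff)
        for pair, value in matrix.pair_values().items()
    }


def effective_cutoff(
    matrix: SimilarityMatrix, cutoff: float = 0.4, quantile: float | None = None
) -> float:
    """The cutoff :func:`binarize` would apply to ``matrix``."""
    if quantile is not None:
        return float(np.quantile(matrix.offdiagonal(), quantile))
    return cutoff


def _auc_from_arrays(labels: np.ndarray, scores: np.ndarray) -> float:
    """Mann-Whitney AUC: midranks give ties a 1/2 contribution."""
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    ranks = rankdata(scores)
    rank_sum = float(ranks[labels == 1].sum())
    return (rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def roc_auc(
    labels: Mapping[Pair, int], scores: Mapping[Pair, float]
) -> float:
    """ROC-AUC of ``scores`` against binary ``labels`` over identical keys.

    Equivalent to the fraction of (positive, negative) pair comparisons the
    scores order correctly, counting ties as 1/2.
    """
    if set(labels) != set(scores):
        only_l = set(labels) - set(scores)
        only_s = set(scores) - set(labels)
        raise ValueError(
            f"label/score key sets differ ({len(only_l)} only in labels, "
            f"{len(only_s)} only in scores)"
        )
    keys = list(labels)
    y = np.array([labels[k] for k in keys], dtype=int)
    s = np.array([scores[k] for k in keys], dtype=float)
    if not (y == 1).any():
        raise ValueError("no positive labels; AUC undefined")
    if not (y == 0).any():
        raise ValueError("no negative labels; AUC undefined")
    return _auc_from_arrays(y, s)


def prank_score(
    sim_a: SimilarityMatrix,
    sim_b: SimilarityMatrix,
    cutoff: float = 0.4,
    quantile: float | None = None,
) -> PRankResult:
    """Symmetrized PRank concordance of two systems' similarity matrices.

    Compound sets are intersected automatically (logged); each system is then
    binarized at the cutoff (or at its own quantile in quantile mode) and
    scored by the other system's similarities.
    """
    common = [c for c in sim_a.compound_ids if c in set(sim_b.compound_ids)]
    if len(common) < 2:
        raise ValueError(
            f"systems {sim_a.system_id!r} and {sim_b.system_id!r} share "
            f"{len(common)} compound(s); need at least 2"
        )
    if len(common) < sim_a.n_compounds or len(common) < sim_b.n_compounds:
        logger.info(
            "intersecting %r (%d) and %r (%d) to %d common compounds",
            sim_a.system_id, sim_a.n_compounds,
            sim_b.system_id, sim_b.n_compounds, len(common),
        )
    a = sim_a.restrict(common)
    b = sim_b.restrict(common)

    labels_a = binarize(a, cutoff=cutoff, quantile=quantile)
    labels_b = binarize(b, cutoff=cutoff, quantile=quantile)
    scores_a = a.pair_values()
    scores_b = b.pair_values()

    def _one_direction(labels, scores, label_system):
        try:
            return roc_auc(labels, scores)
        except ValueError as exc:
            logger.warning(
                "AUC undefined with %s labels: %s", label_system, exc
            )
            return None

    auc_a = _one_direction(labels_a, scores_b, sim_a.system_id)
    auc_b = _one_direction(labels_b, scores_a, sim_b.system_id)

    defined = [x for x in (auc_a, auc_b) if x is not None]
    score = float(np.mean(defined)) if defined else None
    return PRankResult(
        system_pair=(sim_a.system_id, sim_b.system_id),
        cutoff_a=effective_cutoff(a, cutoff, quantile),
        cutoff_b=effective_cutoff(b, cutoff, quantile),
        auc_a_labels=auc_a,
        auc_b_labels=auc_b,
        prank_score=score,
        n_pairs=len(common) * (len(common) - 1) // 2,
        n_positive_a=sum(labels_a.values()),
        n_positive_b=sum(labels_b.values()),
        partial=len(defined) < 2,
    )


def prank_by_geneset(
    systems: Sequence[FoldChangeMatrix],
    gene_sets: GeneSetCollection,
    fc_threshold: float = 1.5,
    cutoff: float = 0.4,
    quantile: float | None = None,
    fixed_denominator: int | None = None,
) -> dict[tuple[str, tuple[str, str]], PRankResult]:
    """Per-pathway PRank concordance for every system pair.

    For each pathway, threshold-mode signatures restricted to its genes are
    built in every system, turned into pairwise Dice matrices and compared
    with :func:`prank_score`.  Pathways where a direction is single-class are
    reported with the ``partial`` flag (or a ``None`` score when both
    directions are degenerate), never silently dropped.
    """
    if len(systems) < 2:
        raise ValueError("need at least two systems")
    results: dict[tuple[str, tuple[str, str]], PRankResult] = {}
    for pid in gene_sets.pathway_ids:
        genes = gene_sets.genes(pid)
        sims = {}
        for m in systems:
            sigs = [
                make_geneset_signature(m, c, genes, fc_threshold=fc_threshold)
                for c in m.compound_ids
            ]
            sims[m.system_id] = pairwise_similarity(
                sigs, m.system_id, fixed_denominator=fixed_denominator
            )
        for sa, sb in itertools.combinations(sims, 2):
            results[(pid, (sa, sb))] = prank_score(
                sims[sa], sims[sb], cutoff=cutoff, quantile=quantile
            )
    return results


def top_pathways(
    results: Mapping[tuple[str, tuple[str, str]], PRankResult], top_n: int = 15
) -> dict[tuple[str, str], list[str]]:
    """Top pathways per system pair ranked by PRank score (ties by id).

    Pathways with an undefined score rank last.
    """
    by_pair: dict[tuple[str, str], list[tuple[str, float]]] = {}
    for (pid, pair), res in results.items():
        score = res.prank_score if res.prank_score is not None else -np.inf
        by_pair.setdefault(pair, []).append((pid, score))
    out = {}
    for pair, entries in by_pair.items():
        entries.sort(key=lambda e: (-e[1], e[0]))
        out[pair] = [pid for pid, _ in entries[:top_n]]
    return out


def top_pathway_overlap(
    results: Mapping[tuple[str, tuple[str, str]], PRankResult], top_n: int = 15
) -> dict[frozenset, set[str]]:
    """Venn-style intersections of the per-pair top-pathway lists.

    Returns, for every non-empty combination of system pairs, the pathways
    common to exactly the top lists of those pairs.
    """
    tops = {pair: set(pids) for pair, pids in top_pathways(results, top_n).items()}
    pairs = list(tops)
    regions: dict[frozenset, set[str]] = {}
    for r in range(1, len(pairs) + 1):
        for combo in itertools.combinations(pairs, r):
            inside = set.intersection(*(tops[p] for p in combo))
            rest = [tops[p] for p in pairs if p not in combo]
            outside = set().union(*rest) if rest else set()
            regions[frozenset(combo)] = inside - outside
    return regions


def geneset_prank_table(
    results: Mapping[tuple[str, tuple[str, str]], PRankResult]
) -> pd.DataFrame:
    """Long-format table of per-pathway PRank results."""
    rows = []
    for (pid, pair), res in sorted(results.items()):
        d = res.to_dict()
        d["pathway_id"] = pid
        rows.append(d)
    cols = ["pathway_id", "system_a", "system_b", "prank_score",
            "auc_a_labels", "auc_b_labels", "n_pairs",
            "n_positive_a", "n_positive_b", "partial", "cutoff_a", "cutoff_b"]
    return pd.DataFrame(rows, columns=cols)


def condition_sweep(
    grids: Mapping[tuple[str, str], Mapping[str, SimilarityMatrix]],
    cutoff: float = 0.4,
    quantile: float | None = None,
) -> pd.DataFrame:
    """PRank per (dose, time) condition for every system pair.

    ``grids`` maps a condition label pair to per-system similarity matrices.
    Returns a long-format table with one row per (condition, system pair);
    undefined directions carry the ``partial`` flag through.
    """
    rows = []
    for (dose, time), sims in grids.items():
        if len(sims) < 2:
            raise ValueError(
                f"condition ({dose}, {time}) has {len(sims)} system(s); "
                f"need at least 2"
            )
        for sa, sb in itertools.combinations(sims, 2):
            res = prank_score(sims[sa], sims[sb], cutoff=cutoff, quantile=quantile)
            row = res.to_dict()
            row["dose"] = dose
            row["time"] = time
            rows.append(row)
    cols = ["dose", "time", "system_a", "system_b", "prank_score",
            "auc_a_labels", "auc_b_labels", "n_pairs",
            "n_positive_a", "n_positive_b", "partial", "cutoff_a", "cutoff_b"]
    return pd.DataFrame(rows, columns=cols)
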
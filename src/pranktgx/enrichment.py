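"""Pathway over-representation analysis and the POP concordance statistic.

Each compound's combined signature (up and down pooled, 2k genes) is tested
for over-representation in every pathway with the one-sided hypergeometric
(Fisher's exact) test against the universe of measured genes; p-values are
Benjamini-Hochberg adjusted across pathways within each compound.  Pathways
are then ranked per system by perturbation frequency — the number of
compounds in which they are significant at the adjusted level alpha — and two
systems are compared by the percentage of overlapping pathways,

    POP(L) = |top-L(A) ∩ top-L(B)| / L,

over a range of list depths L (default 5..60), summarized by the mean over L.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import FoldChangeMatrix, GeneSetCollection
from .signatures import make_signature

logger = logging.getLogger(__name__)


def fisher_enrich(
    signature_genes: set[str] | frozenset[str],
    pathway_genes: set[str] | frozenset[str],
    universe: set[str] | frozenset[str],
) -> tuple[int, int, int, int, float]:
    """One-sided over-representation test of a signature in a pathway.

    Returns ``(k, K, n, N, p)`` where ``N`` is the universe size, ``K`` the
    pathway size within the universe, ``n`` the signature size, ``k`` their
    overlap, and ``p = P(X >= k)`` under the hypergeometric null of drawing
    ``n`` genes from the universe.
    """
    if not universe:
        raise ValueError("empty gene universe")
    signature_genes = set(signature_genes)
    if not signature_genes <= set(universe):
        extra = sorted(signature_genes - set(universe))[:5]
        raise ValueError(f"signature genes outside universe: {extra}")
    pathway_in = set(pathway_genes) & set(universe)
    N = len(universe)
    K = len(pathway_in)
    n = len(signature_genes)
    k = len(signature_genes & pathway_in)
    # upper tail including k: survival function at k-1
    p = float(hypergeom.sf(k - 1, N, K, n))
    return k, K, n, N, min(p, 1.0)


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if ((p <= 0) | (p > 1)).any():
        bad = p[(p <= 0) | (p > 1)][0]
        raise ValueError(f"p-value {bad} outside (0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return [float(x) for x in adjusted]


@dataclass
class RankedPathwayList:
    """Pathways of one system ordered by descending perturbation frequency.

    Frequency = number of compounds in which the pathway is significant.
    Ties are broken by ascending pathway id, so the order is deterministic.
    """

    system_id: str
    pathway_ids: list[str]
    frequencies: list[int]

    def __post_init__(self) -> None:
        if len(self.pathway_ids) != len(self.frequencies):
            raise ValueError("pathway_ids and frequencies differ in length")
        freqs = np.asarray(self.frequencies)
        if (np.diff(freqs) > 0).any():
            raise ValueError("frequencies must be non-increasing")

    def top(self, L: int) -> list[str]:
        return self.pathway_ids[:L]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.pathway_ids) + 1),
                "pathway_id": self.pathway_ids,
                "frequency": self.frequencies,
            }
        )


@dataclass
class EnrichmentResult:
    """Per-(compound, pathway) enrichment table plus the frequency ranking."""

    system_id: str
    table: pd.DataFrame
    ranking: RankedPathwayList
    alpha: float


def enrich_system(
    matrix: FoldChangeMatrix,
    gene_sets: GeneSetCollection,
    k: int = 200,
    alpha: float = 0.05,
) -> EnrichmentResult:
    """ORA of every compound's 2k-gene signature against every pathway.

    The universe is the set of genes measured in ``matrix``.  BH adjustment is
    applied across pathways within each compound (the family a per-compound
    enrichment query induces).  The ranking counts, per pathway, the
    compounds with adjusted p <= alpha.
    """
    universe = set(matrix.gene_ids)
    n_universe = len(universe)
    pids = gene_sets.pathway_ids
    if not pids:
        raise ValueError("empty gene-set collection")
    pathway_in = {pid: gene_sets.genes(pid) & universe for pid in pids}

    rows = []
    sig_counts = {pid: 0 for pid in pids}
    for compound in matrix.compound_ids:
        sig = make_signature(matrix, compound, k=k)
        genes = sig.up | sig.down
        n_sig = len(genes)
        ks, Ks, ps = [], [], []
        for pid in pids:
            overlap = len(genes & pathway_in[pid])
            K = len(pathway_in[pid])
            p = float(hypergeom.sf(overlap - 1, n_universe, K, n_sig))
            ks.append(overlap)
            Ks.append(K)
            ps.append(min(p, 1.0))
        adj = bh_adjust(ps)
        for pid, kk, KK, p, q in zip(pids, ks, Ks, ps, adj):
            significant = q <= alpha
            if significant:
                sig_counts[pid] += 1
            rows.append(
                {
                    "compound_id": compound,
                    "pathway_id": pid,
                    "overlap": kk,
                    "pathway_size": KK,
                    "signature_size": n_sig,
                    "universe_size": n_universe,
                    "p_value": p,
                    "adjusted_p": q,
                    "significant": significant,
                }
            )

    order = sorted(pids, key=lambda pid: (-sig_counts[pid], pid))
    ranking = RankedPathwayList(
        system_id=matrix.system_id,
        pathway_ids=order,
        frequencies=[sig_counts[pid] for pid in order],
    )
    return EnrichmentResult(
        system_id=matrix.system_id,
        table=pd.DataFrame(rows),
        ranking=ranking,
        alpha=alpha,
    )


@dataclass
class POPCurve:
    """Percentage of overlapping pathways between two systems over depths L."""

    system_pair: tuple[str, str]
    L_values: list[int]
    pop_values: list[float]

    @property
    def summary(self) -> float:
        """Mean POP over the computed L values."""
        return float(np.mean(self.pop_values))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"L": self.L_values, "pop": self.pop_values})


def pop(
    list_a: RankedPathwayList,
    list_b: RankedPathwayList,
    L_range: Iterable[int] = range(5, 61),
) -> POPCurve:
    """POP(L) = |top-L(a) ∩ top-L(b)| / L for each L in ``L_range``.

    If either list is shorter than max(L), the range is truncated to the
    shorter list (logged).  Symmetric in its two arguments.
    """
    if not list_a.pathway_ids or not list_b.pathway_ids:
        raise ValueError("cannot compute POP on an empty pathway list")
    Ls = sorted(set(int(L) for L in L_range))
    if not Ls or Ls[0] < 1:
        raise ValueError("L values must be positive")
    shortest = min(len(list_a.pathway_ids), len(list_b.pathway_ids))
    usable = [L for L in Ls if L <= shortest]
    if len(usable) < len(Ls):
        logger.info(
            "truncating POP depths to L <= %d (shorter ranked list)", shortest
        )
    if not usable:
        # both lists shorter than every requested depth: compare full lists
        logger.info(
            "all requested L exceed the shorter ranked list (%d); using its "
            "full length", shortest,
        )
        usable = [shortest]
    pops = [
        len(set(list_a.top(L)) & set(list_b.top(L))) / L for L in usable
    ]
    return POPCurve(
        system_pair=(list_a.system_id, list_b.system_id),
        L_values=usable,
        pop_values=pops,
    )
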
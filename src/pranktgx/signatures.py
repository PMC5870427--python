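"""Directional compound signatures from fold-change profiles.

Two signature forms are used downstream:

* **top-k** — the k genes with the largest and the k genes with the smallest
  log2 fold change (default k=200, i.e. a 400-gene signature), mirroring
  connectivity-map-style signature matching;
* **threshold** — restricted to a pathway gene set, keeping genes whose
  fold-change ratio exceeds a threshold in either direction
  (|log2 FC| > log2(threshold), default threshold 1.5).

No variance model or per-gene p-value is involved: genes are ranked purely by
fold change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .io import FoldChangeMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Signature:
    """Per-compound directional gene sets.

    ``up`` and ``down`` are disjoint.  In ``"topk"`` mode both sets have
    exactly ``k`` genes; in ``"threshold"`` mode sizes are data-dependent and
    may be zero.
    """

    compound_id: str
    up: frozenset[str]
    down: frozenset[str]
    mode: str = "topk"

    def __post_init__(self) -> None:
        if self.mode not in ("topk", "threshold"):
            raise ValueError(f"unknown signature mode {self.mode!r}")
        overlap = self.up & self.down
        if overlap:
            raise ValueError(
                f"signature for {self.compound_id!r} has genes in both "
                f"directions: {sorted(overlap)[:5]}"
            )
        if self.mode == "topk" and len(self.up) != len(self.down):
            raise ValueError(
                f"topk signature for {self.compound_id!r} has unequal "
                f"direction sizes {len(self.up)} vs {len(self.down)}"
            )

    @property
    def k(self) -> int:
        if self.mode != "topk":
            raise ValueError("k is only defined for topk signatures")
        return len(self.up)

    @property
    def size(self) -> int:
        return len(self.up) + len(self.down)


def _ranked_gene_order(values: np.ndarray, gene_ids: np.ndarray) -> np.ndarray:
    """Indices sorting by ascending value, ties by ascending gene id."""
    # np.lexsort sorts by the last key first
    return np.lexsort((gene_ids, values))


def make_signature(
    matrix: FoldChangeMatrix, compound_id: str, k: int = 200
) -> Signature:
    """Top/bottom-k directional signature of one compound.

    ``up`` holds the k genes with the largest log2 fold change, ``down`` the k
    genes with the smallest.  Ties at either boundary are broken by ascending
    lexicographic gene id; in the degenerate case where a tie spans both
    boundaries, the down set is filled from genes not already claimed by up so
    the two directions stay disjoint.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if matrix.n_genes < 2 * k:
        raise ValueError(
            f"matrix has {matrix.n_genes} genes; top/bottom-{k} signatures "
            f"require at least {2 * k}"
        )
    profile = matrix.profile(compound_id)
    gene_ids = profile.index.to_numpy(dtype=object)
    values = profile.to_numpy(dtype=float)

    asc = _ranked_gene_order(values, gene_ids)
    desc = _ranked_gene_order(-values, gene_ids)
    up = frozenset(gene_ids[desc[:k]])
    down_order = [g for g in gene_ids[asc] if g not in up]
    down = frozenset(down_order[:k])
    return Signature(compound_id=compound_id, up=up, down=down, mode="topk")


def make_signatures(
    matrix: FoldChangeMatrix, k: int = 200, compound_ids: Iterable[str] | None = None
) -> list[Signature]:
    """Top/bottom-k signatures for every (or the given) compound in a matrix."""
    ids = list(compound_ids) if compound_ids is not None else matrix.compound_ids
    return [make_signature(matrix, c, k=k) for c in ids]


def make_geneset_signature(
    matrix: FoldChangeMatrix,
    compound_id: str,
    gene_set: Iterable[str],
    fc_threshold: float = 1.5,
) -> Signature:
    """Threshold signature restricted to a pathway gene set.

    Keeps measured genes in ``gene_set`` with fold change beyond
    ``fc_threshold`` on the ratio scale in either direction:
    up if log2 FC > log2(fc_threshold), down if log2 FC < -log2(fc_threshold)
    (strict inequalities).  Genes in the set but absent from the matrix are
    ignored; an empty intersection yields a valid empty signature.
    """
    if fc_threshold <= 1:
        raise ValueError("fc_threshold must be > 1 on the ratio scale")
    profile = matrix.profile(compound_id)
    restricted = profile[profile.index.isin(set(gene_set))]
    if restricted.empty:
        logger.warning(
            "gene set shares no genes with matrix %r; empty signature for %r",
            matrix.system_id, compound_id,
        )
    cut = np.log2(fc_threshold)
    up = frozenset(restricted.index[restricted.to_numpy() > cut])
    down = frozenset(restricted.index[restricted.to_numpy() < -cut])
    return Signature(compound_id=compound_id, up=up, down=down, mode="threshold")


def write_signatures(signatures: Iterable[Signature], path) -> None:
    """Serialize signatures as TSV: compound_id, direction, gene_id."""
    with open(path, "w") as fh:
        fh.write("compound_id\tdirection\tgene_id\n")
        for sig in signatures:
            for gene in sorted(sig.up):
                fh.write(f"{sig.compound_id}\tup\t{gene}\n")
            for gene in sorted(sig.down):
                fh.write(f"{sig.compound_id}\tdown\t{gene}\n")
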
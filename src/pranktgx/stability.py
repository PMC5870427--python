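"""Therapeutic-category discrimination via stability ratios.

For a focal ATC level-2 category the stability ratio is

    ratio = mean(Dice over within-category pairs)
          / mean(Dice over across-category pairs)

A ratio above 1 means compounds sharing the therapeutic category look more
alike transcriptomically than compounds from different categories, i.e. the
assay system can discriminate that category.

Multi-label compounds are handled conservatively: a pair is "within" the
focal category when both compounds carry its code; a pair is "across" when
exactly one compound carries the code and the two compounds share *no*
level-2 code at all.  Pairs that share some other code are ambiguous
(overlapping therapeutic uses such as antibacterials that are also
ophthalmologicals) and are excluded from the contrast.

The across pool is per focal category by default; a ``global`` mode using all
zero-shared-code annotated pairs is also available, and the choice is
recorded in the result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .io import CompoundAnnotation
from .similarity import SimilarityMatrix

logger = logging.getLogger(__name__)


@dataclass
class StabilityResult:
    """Stability ratio of one category in one assay system."""

    system_id: str
    category: str
    n_members: int
    n_inter_pairs: int
    n_across_pairs: int
    mean_inter: float
    mean_across: float
    ratio: float | None
    across_mode: str = "per_category"

    def to_dict(self) -> dict:
        return {
            "system_id": self.system_id,
            "category": self.category,
            "n_members": self.n_members,
            "n_inter_pairs": self.n_inter_pairs,
            "n_across_pairs": self.n_across_pairs,
            "mean_inter": self.mean_inter,
            "mean_across": self.mean_across,
            "ratio": self.ratio,
            "across_mode": self.across_mode,
        }


def _codes_of(
    annotations: Mapping[str, CompoundAnnotation], compound_id: str
) -> frozenset[str]:
    ann = annotations.get(compound_id)
    return ann.atc_level2_codes if ann is not None else frozenset()


def stability_ratio(
    matrix: SimilarityMatrix,
    annotations: Mapping[str, CompoundAnnotation],
    category: str,
    min_members: int = 5,
    across_mode: str = "per_category",
) -> StabilityResult:
    """Within- vs. across-category mean-similarity ratio for one category.

    Requires at least ``min_members`` compounds of the matrix to carry the
    category code.  ``across_mode="per_category"`` restricts the across pool
    to pairs involving exactly one member of the focal category;
    ``"global"`` uses every annotated pair sharing no code.
    """
    if across_mode not in ("per_category", "global"):
        raise ValueError(f"unknown across_mode {across_mode!r}")
    ids = matrix.compound_ids
    codes = {c: _codes_of(annotations, c) for c in ids}
    members = [c for c in ids if category in codes[c]]
    if len(members) < min_members:
        raise ValueError(
            f"category {category!r} has {len(members)} annotated member(s) in "
            f"system {matrix.system_id!r}; need at least {min_members}"
        )

    inter, across = [], []
    n = len(ids)
    for i in range(n):
        ci = ids[i]
        for j in range(i + 1, n):
            cj = ids[j]
            in_i = category in codes[ci]
            in_j = category in codes[cj]
            if in_i and in_j:
                inter.append(matrix.values[i, j])
            elif across_mode == "per_category" and (in_i ^ in_j):
                # partner must itself be annotated: unannotated compounds are
                # outside the category analysis altogether
                if codes[ci] and codes[cj] and not (codes[ci] & codes[cj]):
                    across.append(matrix.values[i, j])
            elif across_mode == "global" and not (in_i or in_j):
                if codes[ci] and codes[cj] and not (codes[ci] & codes[cj]):
                    across.append(matrix.values[i, j])

    mean_inter = float(np.mean(inter)) if inter else float("nan")
    mean_across = float(np.mean(across)) if across else float("nan")
    if not across or mean_across == 0:
        logger.warning(
            "category %r in system %r: across-category mean is %s; "
            "ratio undefined", category, matrix.system_id,
            "empty" if not across else "zero",
        )
        ratio = None
    else:
        ratio = mean_inter / mean_across
    return StabilityResult(
        system_id=matrix.system_id,
        category=category,
        n_members=len(members),
        n_inter_pairs=len(inter),
        n_across_pairs=len(across),
        mean_inter=mean_inter,
        mean_across=mean_across,
        ratio=ratio,
        across_mode=across_mode,
    )


def stability_table(
    matrices: list[SimilarityMatrix],
    annotations: Mapping[str, CompoundAnnotation],
    min_members: int = 5,
    across_mode: str = "per_category",
) -> pd.DataFrame:
    """One row per (system, qualifying category).

    Categories with fewer than ``min_members`` members in a system are
    omitted with a logged note.
    """
    rows = []
    for matrix in matrices:
        present = {
            code
            for c in matrix.compound_ids
            for code in _codes_of(annotations, c)
        }
        for category in sorted(present):
            members = [
                c for c in matrix.compound_ids
                if category in _codes_of(annotations, c)
            ]
            if len(members) < min_members:
                logger.info(
                    "skipping category %r in system %r (%d < %d members)",
                    category, matrix.system_id, len(members), min_members,
                )
                continue
            rows.append(
                stability_ratio(
                    matrix, annotations, category,
                    min_members=min_members, across_mode=across_mode,
                ).to_dict()
            )
    cols = ["system_id", "category", "n_members", "n_inter_pairs",
            "n_across_pairs", "mean_inter", "mean_across", "ratio",
            "across_mode"]
    return pd.DataFrame(rows, columns=cols)
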
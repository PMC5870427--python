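"""Direction-aware Dice similarity between compound signatures.

For two top-k signatures the similarity is

    Dice(i, j) = (N_up + N_down) / (2k)

where N_up and N_down count genes shared by the up sets and by the down sets
respectively (at k=200 this is the 2(N_up + N_down)/(400+400) form).  Genes
up-regulated by one compound and down-regulated by the other contribute
nothing — overlap is counted per direction, with no penalty term.

For threshold-mode signatures, whose sizes vary, the generalized Dice form
2(N_up + N_down) / (|up_i| + |down_i| + |up_j| + |down_j|) is the default; the
fixed 2k denominator is available via ``fixed_denominator`` for comparability
with top-k analyses.  Two empty signatures score 0 (no evidence of
similarity).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ChemicalSimilarityTable
from .signatures import Signature

logger = logging.getLogger(__name__)


@dataclass
class SimilarityMatrix:
    """Symmetric compound x compound Dice coefficients within one system.

    The diagonal is 1 by definition and is excluded from every mean and from
    all downstream ranking; only distinct pairs carry information.
    """

    system_id: str
    compound_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.compound_ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{n} compound ids"
            )
        if len(set(self.compound_ids)) != n:
            raise ValueError("duplicate compound ids in similarity matrix")
        if not np.allclose(self.values, self.values.T, atol=0, rtol=0):
            raise ValueError("similarity matrix is not symmetric")
        if ((self.values < 0) | (self.values > 1)).any():
            raise ValueError("similarity values outside [0, 1]")

    @property
    def n_compounds(self) -> int:
        return len(self.compound_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.compound_ids, columns=self.compound_ids
        )

    def value(self, a: str, b: str) -> float:
        i = self.compound_ids.index(a)
        j = self.compound_ids.index(b)
        return float(self.values[i, j])

    def pair_values(self) -> dict[frozenset[str], float]:
        """All unordered distinct pairs mapped to their similarity."""
        ids = self.compound_ids
        out: dict[frozenset[str], float] = {}
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                out[frozenset((ids[i], ids[j]))] = float(self.values[i, j])
        return out

    def offdiagonal(self) -> np.ndarray:
        """Strict upper-triangle values as a flat array."""
        iu = np.triu_indices(self.n_compounds, k=1)
        return self.values[iu]

    def restrict(self, compound_ids: Sequence[str]) -> "SimilarityMatrix":
        keep = [c for c in self.compound_ids if c in set(compound_ids)]
        idx = [self.compound_ids.index(c) for c in keep]
        return SimilarityMatrix(
            self.system_id, keep, self.values[np.ix_(idx, idx)]
        )

    def write_square(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="compound_id",
                               float_format="%.17g")

    def write_long(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("compound_i\tcompound_j\tdice\n")
            ids = self.compound_ids
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    fh.write(f"{ids[i]}\t{ids[j]}\t{self.values[i, j]:.17g}\n")


def read_similarity_matrix(path: str | Path, system_id: str) -> SimilarityMatrix:
    """Read a square TSV written by :meth:`SimilarityMatrix.write_square`."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row and column compound ids differ")
    return SimilarityMatrix(system_id, list(df.index), df.to_numpy(dtype=float))


def dice(
    sig_a: Signature, sig_b: Signature, fixed_denominator: int | None = None
) -> float:
    """Direction-aware Dice coefficient between two signatures in [0, 1].

    Top-k signatures must share the same k.  For threshold-mode signatures the
    generalized denominator (sum of the four set sizes) is used unless
    ``fixed_denominator`` gives an explicit total (e.g. 800 for comparability
    with 400-gene signatures).
    """
    n_shared = len(sig_a.up & sig_b.up) + len(sig_a.down & sig_b.down)
    if fixed_denominator is not None:
        if fixed_denominator <= 0:
            raise ValueError("fixed_denominator must be positive")
        return 2 * n_shared / fixed_denominator
    if sig_a.mode == "topk" and sig_b.mode == "topk":
        if sig_a.k != sig_b.k:
            raise ValueError(
                f"cannot compare topk signatures with k={sig_a.k} and "
                f"k={sig_b.k}"
            )
        return n_shared / (2 * sig_a.k)
    total = sig_a.size + sig_b.size
    if total == 0:
        logger.debug(
            "both signatures empty (%r, %r); Dice defined as 0",
            sig_a.compound_id, sig_b.compound_id,
        )
        return 0.0
    return 2 * n_shared / total


def pairwise_similarity(
    signatures: Sequence[Signature],
    system_id: str,
    fixed_denominator: int | None = None,
) -> SimilarityMatrix:
    """All-pairs Dice similarity for one assay system.

    Computed with vectorized membership-matrix intersections; equivalent to
    calling :func:`dice` on every unordered pair.
    """
    if len(signatures) < 2:
        raise ValueError("need at least two signatures")
    ids = [s.compound_id for s in signatures]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate compound ids among signatures")
    modes = {s.mode for s in signatures}
    if modes == {"topk"}:
        ks = {s.k for s in signatures}
        if len(ks) > 1:
            raise ValueError(f"mixed topk sizes {sorted(ks)}")

    universe = sorted(set().union(*(s.up | s.down for s in signatures)))
    gene_idx = {g: i for i, g in enumerate(universe)}
    n, g = len(signatures), len(universe)
    up = np.zeros((n, g), dtype=bool)
    down = np.zeros((n, g), dtype=bool)
    for i, s in enumerate(signatures):
        up[i, [gene_idx[x] for x in s.up]] = True
        down[i, [gene_idx[x] for x in s.down]] = True

    shared = (up.astype(np.int32) @ up.T.astype(np.int32)) + (
        down.astype(np.int32) @ down.T.astype(np.int32)
    )
    if fixed_denominator is not None:
        values = 2 * shared / fixed_denominator
    elif modes == {"topk"}:
        values = shared / (2 * signatures[0].k)
    else:
        sizes = up.sum(axis=1) + down.sum(axis=1)
        denom = sizes[:, None] + sizes[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            values = np.where(denom > 0, 2 * shared / np.maximum(denom, 1), 0.0)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(system_id=system_id, compound_ids=ids, values=values)


def mean_similarity(matrix: SimilarityMatrix) -> float:
    """Arithmetic mean Dice over all distinct pairs (diagonal excluded)."""
    if matrix.n_compounds < 2:
        raise ValueError("mean similarity needs at least two compounds")
    return float(matrix.offdiagonal().mean())


def chem_tgx_correlation(
    tgx: SimilarityMatrix,
    chem: ChemicalSimilarityTable,
    chem_cutoff: float = 0.2,
) -> tuple[float, int]:
    """Pearson correlation of chemical vs. transcriptomic pair similarity.

    Only unordered pairs present in both inputs with chemical similarity
    strictly above ``chem_cutoff`` enter.  Returns ``(r, n_pairs)``.
    """
    tgx_pairs = tgx.pair_values()
    xs, ys = [], []
    for pair, chem_value in chem.entries.items():
        if chem_value > chem_cutoff and pair in tgx_pairs:
            xs.append(chem_value)
            ys.append(tgx_pairs[pair])
    if len(xs) < 3:
        raise ValueError(
            f"only {len(xs)} pair(s) survive the chemical-similarity filter "
            f"(> {chem_cutoff}); need at least 3 for a correlation"
        )
    r, _ = stats.pearsonr(xs, ys)
    return float(r), len(xs)
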
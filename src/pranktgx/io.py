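"""Shared data types, file readers/writers and identifier mapping.

All on-disk formats are plain text:

* fold-change matrices — TSV, genes in rows (first column), compounds in the
  header row;
* gene sets — GMT (name, description, member genes, tab-separated);
* homology map — two-column TSV (source id, target id), no header;
* compound annotations — TSV (compound id, ``;``-separated ATC level-2 codes);
* chemical similarity — three-column TSV (compound_i, compound_j, similarity).

The canonical fold-change scale inside the package is log2, so that up- and
down-regulation are symmetric around zero.  Readers accept either
``scale="log2"`` (values stored as-is) or ``scale="ratio"`` (values
log2-transformed on load; non-positive ratios are rejected).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_ATC2_RE = re.compile(r"^[A-Z]\d{2}$")


class DataError(ValueError):
    """Malformed or inconsistent input data."""


# ---------------------------------------------------------------------------
# Fold-change matrices
# ---------------------------------------------------------------------------


@dataclass
class FoldChangeMatrix:
    """Genes x compounds log2 fold changes for one assay system/condition.

    Parameters
    ----------
    system_id
        Assay-system label, e.g. ``"InVitro"``, ``"InVivo_S"``, ``"InVivo_R"``.
    condition
        ``(dose level, duration)`` label pair, e.g. ``("high", "24h")``.
    data
        DataFrame indexed by gene id with compound ids as columns; values are
        log2 fold changes of treatment vs. matched control.
    """

    system_id: str
    condition: tuple[str, str]
    data: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise DataError(f"duplicate gene id {dup!r} in system {self.system_id!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise DataError(
                f"duplicate compound id {dup!r} in system {self.system_id!r}"
            )
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise DataError(
                f"non-finite fold change at gene {idx[i]!r}, compound {cols[j]!r}"
            )
        self.data = self.data.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def compound_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    def profile(self, compound_id: str) -> pd.Series:
        """Log2 fold-change vector of one compound (genes as index)."""
        if compound_id not in self.data.columns:
            raise KeyError(
                f"compound {compound_id!r} not in system {self.system_id!r}"
            )
        return self.data[compound_id]

    def restrict_compounds(self, compound_ids: Iterable[str]) -> "FoldChangeMatrix":
        keep = [c for c in self.compound_ids if c in set(compound_ids)]
        return FoldChangeMatrix(self.system_id, self.condition, self.data[keep])


def read_fold_change_matrix(
    path: str | Path,
    system_id: str,
    condition: tuple[str, str] = ("high", "longest"),
    scale: str = "log2",
) -> FoldChangeMatrix:
    """Read a genes x compounds TSV into a :class:`FoldChangeMatrix`.

    ``scale="ratio"`` declares the stored values as plain fold-change ratios;
    they are log2-transformed, and non-positive ratios raise :class:`DataError`.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        values = df.to_numpy(dtype=float)
    except ValueError:
        for j, col in enumerate(df.columns):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = df.index[bad][0]
                raise DataError(
                    f"non-numeric value at gene {row!r}, compound {col!r} in {path}"
                ) from None
        raise
    if scale == "ratio":
        if (values <= 0).any():
            i, j = np.argwhere(values <= 0)[0]
            raise DataError(
                f"non-positive ratio {values[i, j]} at gene {df.index[i]!r}, "
                f"compound {df.columns[j]!r} (ratio-scale input must be > 0)"
            )
        df = np.log2(df)
    elif scale != "log2":
        raise ValueError(f"scale must be 'log2' or 'ratio', got {scale!r}")
    return FoldChangeMatrix(system_id=system_id, condition=condition, data=df)


def write_fold_change_matrix(matrix: FoldChangeMatrix, path: str | Path) -> None:
    """Write the matrix as TSV (full float precision round-trips)."""
    matrix.data.to_csv(path, sep="\t", index_label="gene_id", float_format="%.17g")


# ---------------------------------------------------------------------------
# Compound annotations (ATC level-2 therapeutic categories)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CompoundAnnotation:
    """A compound and its ATC level-2 therapeutic-category codes.

    A compound may carry several codes (multiple therapeutic uses) or none;
    unannotated compounds take part in similarity but are excluded from the
    category analysis.
    """

    compound_id: str
    atc_level2_codes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for code in self.atc_level2_codes:
            if not _ATC2_RE.match(code):
                raise DataError(
                    f"invalid ATC level-2 code {code!r} for compound "
                    f"{self.compound_id!r} (expected letter + two digits)"
                )


def read_annotations(path: str | Path) -> dict[str, CompoundAnnotation]:
    """Read a TSV of ``compound_id<TAB>code1;code2;...`` (codes may be empty)."""
    annotations: dict[str, CompoundAnnotation] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            compound_id = parts[0].strip()
            if not compound_id:
                raise DataError(f"{path}:{lineno}: empty compound id")
            if compound_id in annotations:
                raise DataError(
                    f"{path}:{lineno}: duplicate compound {compound_id!r}"
                )
            raw = parts[1].strip() if len(parts) > 1 else ""
            codes = frozenset(c.strip() for c in raw.split(";") if c.strip())
            annotations[compound_id] = CompoundAnnotation(compound_id, codes)
    return annotations


# ---------------------------------------------------------------------------
# Homology mapping and gene-set collections
# ---------------------------------------------------------------------------


@dataclass
class HomologyMap:
    """Many-to-many gene homology mapping (e.g. human -> rat Entrez ids).

    Translation maps every source id to all of its targets, passes ids already
    in the target namespace through unchanged, and drops ids in neither
    namespace (no homolog).  Translating twice therefore equals translating
    once.
    """

    pairs: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        fwd: dict[str, set[str]] = {}
        for src, tgt in self.pairs:
            fwd.setdefault(src, set()).add(tgt)
        self._forward = fwd
        self._targets = {tgt for _, tgt in self.pairs}

    def translate(self, genes: Iterable[str]) -> frozenset[str]:
        out: set[str] = set()
        for g in genes:
            if g in self._forward:
                out |= self._forward[g]
            elif g in self._targets:
                out.add(g)
        return frozenset(out)


def read_homology_map(path: str | Path) -> HomologyMap:
    """Read a headerless two-column TSV of (source gene id, target gene id)."""
    pairs: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise DataError(f"{path}:{lineno}: expected two columns")
            pairs.add((parts[0].strip(), parts[1].strip()))
    return HomologyMap(frozenset(pairs))


@dataclass
class GeneSetCollection:
    """Named pathway gene sets after homology mapping and size filtering.

    Only sets strictly larger than ``min_size`` genes are retained (default
    200), so that gene-set-restricted signatures have enough genes to be
    informative.
    """

    sets: dict[str, tuple[str, frozenset[str]]]
    min_size: int = 200

    def __post_init__(self) -> None:
        for pid, (_, genes) in self.sets.items():
            if len(genes) <= self.min_size:
                raise DataError(
                    f"gene set {pid!r} has {len(genes)} genes; the collection "
                    f"requires more than {self.min_size}"
                )

    @property
    def pathway_ids(self) -> list[str]:
        return sorted(self.sets)

    def genes(self, pathway_id: str) -> frozenset[str]:
        return self.sets[pathway_id][1]

    def name(self, pathway_id: str) -> str:
        return self.sets[pathway_id][0]

    def __len__(self) -> int:
        return len(self.sets)

    def translate(self, homology: HomologyMap) -> "GeneSetCollection":
        """Map all member genes through ``homology``; re-apply the size filter."""
        mapped = {
            pid: (name, homology.translate(genes))
            for pid, (name, genes) in self.sets.items()
        }
        kept = {
            pid: (name, genes)
            for pid, (name, genes) in mapped.items()
            if len(genes) > self.min_size
        }
        dropped = len(mapped) - len(kept)
        if dropped:
            logger.info("homology mapping dropped %d set(s) below size filter", dropped)
        return GeneSetCollection(kept, self.min_size)


def read_gene_sets(
    path: str | Path,
    homology: HomologyMap | None = None,
    min_size: int = 200,
) -> GeneSetCollection:
    """Read a GMT file, optionally mapping members through a homology table.

    Each line: ``name<TAB>description<TAB>gene1<TAB>gene2...``.  Sets whose
    mapped membership is not strictly larger than ``min_size`` are dropped.
    """
    raw: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataError(
                    f"{path}:{lineno}: malformed GMT line (need name, "
                    f"description and at least one gene)"
                )
            pid, desc = parts[0], parts[1]
            if pid in raw:
                raise DataError(f"{path}:{lineno}: duplicate gene set {pid!r}")
            genes = frozenset(g for g in parts[2:] if g)
            if homology is not None:
                genes = homology.translate(genes)
            raw[pid] = (desc, genes)
    kept = {
        pid: (name, genes) for pid, (name, genes) in raw.items() if len(genes) > min_size
    }
    if len(kept) < len(raw):
        logger.info(
            "size filter (> %d genes) kept %d of %d gene sets",
            min_size, len(kept), len(raw),
        )
    return GeneSetCollection(kept, min_size)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid in collection.pathway_ids:
            name, genes = collection.sets[pid]
            fh.write("\t".join([pid, name, *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# Chemical similarity
# ---------------------------------------------------------------------------


@dataclass
class ChemicalSimilarityTable:
    """Precomputed pairwise chemical (fingerprint) similarity in [0, 1].

    Keys are unordered compound pairs, so the table is symmetric by
    construction.  Fingerprint computation itself is upstream of this package;
    only the precomputed table is consumed.
    """

    entries: dict[frozenset[str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pair, value in self.entries.items():
            if len(pair) != 2:
                raise DataError(f"chemical-similarity key {set(pair)} is not a pair")
            if not 0.0 <= value <= 1.0:
                raise DataError(
                    f"chemical similarity {value} for pair {sorted(pair)} "
                    f"outside [0, 1]"
                )

    def get(self, a: str, b: str) -> float | None:
        return self.entries.get(frozenset((a, b)))


def read_chemical_similarity(path: str | Path) -> ChemicalSimilarityTable:
    """Read a three-column TSV (compound_i, compound_j, similarity)."""
    entries: dict[frozenset[str], float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataError(f"{path}:{lineno}: expected three columns")
            a, b, raw = parts[0], parts[1], parts[2]
            try:
                value = float(raw)
            except ValueError:
                raise DataError(f"{path}:{lineno}: non-numeric similarity {raw!r}")
            key = frozenset((a, b))
            if len(key) != 2:
                raise DataError(f"{path}:{lineno}: self-pair {a!r}")
            if key in entries and entries[key] != value:
                raise DataError(
                    f"{path}:{lineno}: conflicting duplicate for pair ({a}, {b})"
                )
            entries[key] = value
    return ChemicalSimilarityTable(entries)
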
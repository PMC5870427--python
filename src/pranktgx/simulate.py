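"""Seeded generator of multi-system fold-change data with known ground truth.

The generator emulates the situation the pipeline is built for: several assay
systems (e.g. an in vitro hepatocyte assay and short- and long-duration in
vivo designs) observing noisy versions of shared per-compound transcriptional
effects, with

* a tunable **pairwise latent-signal correlation** ρ between systems — the
  concordance dial that PRank should recover;
* **therapeutic-category structure** — compounds of a category draw a fraction
  α of their latent effect from a shared category prototype, so categories
  with α > 0 are transcriptomically coherent;
* **planted pathway perturbations** — fixed gene sets whose genes receive a
  consistent signed log2 boost in the compounds of affected categories, so
  enrichment and gene-set-restricted analyses have a known answer;
* **decoy pathways** — random gene sets of the same size, for specificity.

Generative model, per compound c (all on the log2 fold-change scale):

    t_c  = [α · p_cat + (1−α) · u_c] / sqrt(α² + (1−α)²)  (+ pathway boosts)
    x_sc = Σ_f  L_sf · f_c^{(f)}          with  f_c^{(1)} = t_c
    y_sc = x_sc + ε,   ε ~ N(0, noise_sd²) i.i.d.

where p_cat and u_c are sparse random fields (a ``signal_sparsity`` fraction
of genes nonzero, N(0, effect_sd²) values), the f_c^{(f)} for f ≥ 2 are
independent sparse fields of the same law, and L is the Cholesky factor of
the configured inter-system correlation matrix R (R_ss' = ρ_ss'), so the
latent signals of systems s and s' correlate at ρ_ss' by construction.
Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    CompoundAnnotation,
    FoldChangeMatrix,
    GeneSetCollection,
    write_fold_change_matrix,
    write_gene_sets,
)

DEFAULT_SYSTEMS = ("InVitro", "InVivo_S", "InVivo_R")
DEFAULT_RHO = (
    ("InVivo_S", "InVivo_R", 0.9),
    ("InVitro", "InVivo_R", 0.7),
    ("InVitro", "InVivo_S", 0.55),
)
DEFAULT_CATEGORIES = (
    ("C10", 6, 0.7),
    ("A02", 6, 0.6),
    ("N02", 6, 0.5),
    ("J01", 6, 0.0),
)
DEFAULT_PLANTED = (
    ("PW_PLANTED_LIPID", 250, ("C10",), 2.0),
    ("PW_PLANTED_ACID", 250, ("A02",), 2.0),
    ("PW_PLANTED_ANALG", 250, ("N02",), 2.0),
)


@dataclass
class SyntheticConfig:
    """Study-design parameters for one synthetic bundle.

    Defaults mirror the study conditions the pipeline is validated under:
    5000 genes, 60 compounds, three systems with latent correlations
    0.9 / 0.7 / 0.55, four six-compound therapeutic categories with category
    weights α = 0.7 / 0.6 / 0.5 / 0.0, and three planted 250-gene pathways at
    effect size 2 (log2) plus ten decoys.
    """

    n_genes: int = 5000
    n_compounds: int = 60
    systems: tuple[str, ...] = DEFAULT_SYSTEMS
    rho: tuple[tuple[str, str, float], ...] = DEFAULT_RHO
    categories: tuple[tuple[str, int, float], ...] = DEFAULT_CATEGORIES
    planted_pathways: tuple[tuple[str, int, tuple[str, ...], float], ...] = (
        DEFAULT_PLANTED
    )
    n_decoy_pathways: int = 10
    decoy_size: int = 250
    noise_sd: float = 0.3
    signal_sparsity: float = 0.1
    effect_sd: float = 2.0
    seed: int = 0

    def correlation_matrix(self) -> np.ndarray:
        """The inter-system latent correlation matrix R (validated)."""
        s = list(self.systems)
        R = np.eye(len(s))
        seen: set[frozenset] = set()
        for a, b, r in self.rho:
            if a not in s or b not in s:
                raise ValueError(f"rho entry references unknown system ({a}, {b})")
            if a == b:
                raise ValueError(f"rho entry for a system with itself: {a}")
            key = frozenset((a, b))
            if key in seen:
                raise ValueError(f"duplicate rho entry for pair ({a}, {b})")
            seen.add(key)
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"rho for ({a}, {b}) is {r}; must be in [0, 1]")
            i, j = s.index(a), s.index(b)
            R[i, j] = R[j, i] = r
        n_pairs = len(s) * (len(s) - 1) // 2
        if len(seen) != n_pairs:
            raise ValueError(
                f"rho must cover all {n_pairs} system pairs; got {len(seen)}"
            )
        return R

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_compounds < 2:
            raise ValueError("need n_genes >= 1 and n_compounds >= 2")
        if not 0 < self.signal_sparsity <= 1:
            raise ValueError("signal_sparsity must be in (0, 1]")
        if self.noise_sd < 0 or self.effect_sd <= 0:
            raise ValueError("noise_sd must be >= 0 and effect_sd > 0")
        if sum(n for _, n, _ in self.categories) > self.n_compounds:
            raise ValueError("category member counts exceed n_compounds")
        for _, n, alpha in self.categories:
            if not 0.0 <= alpha <= 1.0:
                raise ValueError(f"category weight alpha {alpha} outside [0, 1]")
        for pid, size, _, _ in self.planted_pathways:
            if size > self.n_genes:
                raise ValueError(f"planted pathway {pid!r} larger than gene universe")
        _psd_cholesky(self.correlation_matrix())


def _psd_cholesky(R: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Lower-triangular L with L Lᵀ = R, allowing semidefinite R.

    A zero pivot (e.g. two systems at ρ = 1) yields a zero column instead of
    failing, so perfectly correlated systems share factors exactly.  Keeping
    the factorization triangular guarantees every system loads on factor 0,
    the structured latent signal.
    """
    n = R.shape[0]
    L = np.zeros_like(R, dtype=float)
    for i in range(n):
        for j in range(i + 1):
            s = R[i, j] - L[i, :j] @ L[j, :j]
            if i == j:
                if s < -tol:
                    raise ValueError(
                        "inter-system correlation matrix is not positive "
                        "semidefinite"
                    )
                L[i, j] = np.sqrt(max(s, 0.0))
            else:
                L[i, j] = s / L[j, j] if L[j, j] > tol else 0.0
    if not np.allclose(L @ L.T, R, atol=1e-8):
        raise ValueError(
            "inter-system correlation matrix is not positive semidefinite"
        )
    return L


@dataclass
class SyntheticBundle:
    """Generated matrices plus the ground truth that produced them."""

    config: SyntheticConfig
    matrices: dict[str, FoldChangeMatrix]
    annotations: dict[str, CompoundAnnotation]
    gene_sets: GeneSetCollection
    ground_truth: dict

    @property
    def systems(self) -> list[str]:
        return list(self.config.systems)


def _sparse_field(
    rng: np.random.Generator, n_genes: int, sparsity: float, sd: float
) -> np.ndarray:
    """Vector with a ``sparsity`` fraction of N(0, sd²) entries, rest zero."""
    m = max(1, int(round(sparsity * n_genes)))
    out = np.zeros(n_genes)
    support = rng.choice(n_genes, size=m, replace=False)
    out[support] = rng.normal(0.0, sd, size=m)
    return out


def generate(config: SyntheticConfig) -> SyntheticBundle:
    """Generate one multi-system bundle; bit-identical for identical config."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_g, n_c = config.n_genes, config.n_compounds
    width = max(5, len(str(n_g)))
    gene_ids = [f"G{i:0{width}d}" for i in range(n_g)]
    compound_ids = [f"CPD{i:03d}" for i in range(n_c)]

    # category membership: consecutive blocks, remaining compounds unlabelled
    category_of: dict[str, str | None] = {c: None for c in compound_ids}
    members: dict[str, list[str]] = {}
    cursor = 0
    for code, n_members, _ in config.categories:
        block = compound_ids[cursor: cursor + n_members]
        members[code] = block
        for c in block:
            category_of[c] = code
        cursor += n_members
    alpha_of = {code: a for code, _, a in config.categories}

    prototypes = {
        code: _sparse_field(rng, n_g, config.signal_sparsity, config.effect_sd)
        for code, _, _ in config.categories
    }

    # planted pathways: gene subset + fixed per-gene sign pattern
    planted: dict[str, dict] = {}
    for pid, size, affected, effect in config.planted_pathways:
        idx = rng.choice(n_g, size=size, replace=False)
        signs = rng.choice([-1.0, 1.0], size=size)
        planted[pid] = {
            "gene_index": idx,
            "signs": signs,
            "affected_categories": tuple(affected),
            "effect_size": float(effect),
        }

    n_sys = len(config.systems)
    L = _psd_cholesky(config.correlation_matrix())

    latent = np.zeros((n_g, n_c))
    for j, c in enumerate(compound_ids):
        u = _sparse_field(rng, n_g, config.signal_sparsity, config.effect_sd)
        code = category_of[c]
        alpha = alpha_of.get(code, 0.0) if code else 0.0
        if alpha > 0:
            t = (alpha * prototypes[code] + (1 - alpha) * u) / np.sqrt(
                alpha**2 + (1 - alpha) ** 2
            )
        else:
            t = u
        for pid, info in planted.items():
            if code is not None and code in info["affected_categories"]:
                t = t.copy()
                t[info["gene_index"]] += info["signs"] * info["effect_size"]
        latent[:, j] = t

    # independent factors with the same marginal law as the latent signal
    factors = [latent]
    for _ in range(n_sys - 1):
        F = np.column_stack(
            [
                _sparse_field(rng, n_g, config.signal_sparsity, config.effect_sd)
                for _ in range(n_c)
            ]
        )
        factors.append(F)

    matrices: dict[str, FoldChangeMatrix] = {}
    for s_idx, system in enumerate(config.systems):
        signal = sum(L[s_idx, f] * factors[f] for f in range(n_sys))
        observed = signal + rng.normal(0.0, config.noise_sd, size=(n_g, n_c))
        matrices[system] = FoldChangeMatrix(
            system_id=system,
            condition=("high", "longest"),
            data=pd.DataFrame(observed, index=gene_ids, columns=compound_ids),
        )

    annotations = {
        c: CompoundAnnotation(
            c,
            frozenset([category_of[c]]) if category_of[c] else frozenset(),
        )
        for c in compound_ids
    }

    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for pid, info in planted.items():
        sets[pid] = (
            f"planted pathway ({','.join(info['affected_categories'])})",
            frozenset(gene_ids[i] for i in info["gene_index"]),
        )
    for d in range(config.n_decoy_pathways):
        idx = rng.choice(n_g, size=config.decoy_size, replace=False)
        sets[f"PW_DECOY_{d:02d}"] = (
            "decoy pathway",
            frozenset(gene_ids[i] for i in idx),
        )
    min_size = min(200, min(len(g) for _, g in sets.values()) - 1) if sets else 200
    gene_sets = GeneSetCollection(sets, min_size=min_size)

    ground_truth = {
        "seed": config.seed,
        "rho": {f"{a}|{b}": r for a, b, r in config.rho},
        "alpha": alpha_of,
        "category_members": members,
        "planted_pathways": {
            pid: {
                "affected_categories": list(info["affected_categories"]),
                "effect_size": info["effect_size"],
                "n_genes": int(len(info["gene_index"])),
            }
            for pid, info in planted.items()
        },
        "noise_sd": config.noise_sd,
        "signal_sparsity": config.signal_sparsity,
        "effect_sd": config.effect_sd,
    }
    return SyntheticBundle(
        config=config,
        matrices=matrices,
        annotations=annotations,
        gene_sets=gene_sets,
        ground_truth=ground_truth,
    )


@dataclass
class PairOrdering:
    """System pairs ordered by configured latent correlation, best first."""

    pairs: list[tuple[str, str]]
    partial: bool

    def __iter__(self):
        return iter(self.pairs)


def expected_ordering(bundle: SyntheticBundle) -> PairOrdering:
    """Ground-truth concordance ordering of system pairs (ρ descending).

    Equal ρ values make the order partial (flagged), since the generative
    model then implies no preferred ordering between those pairs.
    """
    entries = sorted(
        ((a, b, r) for a, b, r in bundle.config.rho),
        key=lambda e: (-e[2], e[0], e[1]),
    )
    rhos = [r for _, _, r in entries]
    partial = len(set(rhos)) < len(rhos)
    return PairOrdering(pairs=[(a, b) for a, b, _ in entries], partial=partial)


def write_bundle(bundle: SyntheticBundle, out_dir: str | Path) -> None:
    """Write the bundle in the text formats the readers consume.

    Produces ``<system>.fc.tsv`` per system, ``annotations.tsv``,
    ``gene_sets.gmt`` and ``ground_truth.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for system, matrix in bundle.matrices.items():
        write_fold_change_matrix(matrix, out / f"{system}.fc.tsv")
    with open(out / "annotations.tsv", "w") as fh:
        for c, ann in bundle.annotations.items():
            fh.write(f"{c}\t{';'.join(sorted(ann.atc_level2_codes))}\n")
    write_gene_sets(bundle.gene_sets, out / "gene_sets.gmt")
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(bundle.ground_truth, fh, indent=2)
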
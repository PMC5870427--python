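"""Config-driven orchestration of the full concordance analysis.

``run_all`` reproduces the whole analysis on real or synthetic inputs:
per-system signatures and pairwise Dice matrices, mean-similarity summary,
PRank for every system pair, the therapeutic-category stability table,
per-system pathway enrichment with POP curves between systems, per-pathway
gene-set-restricted PRank with top-list intersections, and (when several
conditions are configured) the dose/time condition sweep.  Every intermediate
is written as TSV/JSON so each number in the report can be recomputed by the
individual module operations, and a manifest records parameters, automatic
decisions and stage completeness.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import enrichment, prank, similarity, stability
from .io import (
    FoldChangeMatrix,
    read_annotations,
    read_chemical_similarity,
    read_fold_change_matrix,
    read_gene_sets,
    read_homology_map,
)
from .signatures import make_signatures, write_signatures

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and parameters for one end-to-end run.

    ``systems`` maps system id to the fold-change TSV of the primary
    condition; ``conditions`` optionally maps ``"dose|time"`` labels to such
    per-system path maps for the sweep.  Defaults follow the standard
    analysis: k=200 signature halves, FC threshold 1.5 for gene-set
    signatures, Dice cutoff 0.4, BH alpha 0.05, POP depths 5..60, and at
    least 5 compounds per therapeutic category.
    """

    systems: dict[str, str]
    out_dir: str
    annotations: str | None = None
    gene_sets: str | None = None
    homology: str | None = None
    chemical_similarity: str | None = None
    conditions: dict[str, dict[str, str]] = field(default_factory=dict)
    scale: str = "log2"
    k: int = 200
    fc_threshold: float = 1.5
    cutoff: float = 0.4
    cutoff_quantile: float | None = None
    alpha: float = 0.05
    L_min: int = 5
    L_max: int = 60
    min_members: int = 5
    min_set_size: int = 200
    top_n_pathways: int = 15
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate_paths(self) -> None:
        paths = list(self.systems.values())
        for cond in self.conditions.values():
            paths.extend(cond.values())
        for p in (self.annotations, self.gene_sets, self.homology,
                  self.chemical_similarity):
            if p is not None:
                paths.append(p)
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input file(s): {missing}")


def _load_matrices(
    paths: Mapping[str, str], scale: str, condition: tuple[str, str]
) -> dict[str, FoldChangeMatrix]:
    return {
        system: read_fold_change_matrix(path, system, condition, scale=scale)
        for system, path in paths.items()
    }


def run_all(config: RunConfig) -> dict[str, Any]:
    """Run every configured stage; returns a report dict (also written to disk).

    A stage failure aborts with the stage name and cause; outputs written up
    to that point are kept and the manifest marks the run incomplete.
    """
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"parameters": {
        k: v for k, v in config.__dict__.items() if k != "systems"
    } | {"systems": dict(config.systems)}}
    manifest: dict[str, Any] = {"stages": {}, "complete": False}
    stage = "load"

    def _finish_stage(name: str) -> None:
        manifest["stages"][name] = "ok"
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)

    try:
        matrices = _load_matrices(config.systems, config.scale, ("high", "longest"))
        annotations = (
            read_annotations(config.annotations) if config.annotations else None
        )
        homology = read_homology_map(config.homology) if config.homology else None
        gene_sets = (
            read_gene_sets(config.gene_sets, homology, config.min_set_size)
            if config.gene_sets
            else None
        )
        chem = (
            read_chemical_similarity(config.chemical_similarity)
            if config.chemical_similarity
            else None
        )
        _finish_stage(stage)

        stage = "similarity"
        sims: dict[str, similarity.SimilarityMatrix] = {}
        mean_rows = []
        for system, matrix in matrices.items():
            sigs = make_signatures(matrix, k=config.k)
            write_signatures(sigs, out / f"{system}.signatures.tsv")
            sim = similarity.pairwise_similarity(sigs, system)
            sim.write_square(out / f"{system}.similarity.tsv")
            sim.write_long(out / f"{system}.similarity.long.tsv")
            sims[system] = sim
            mean_rows.append(
                {"system_id": system,
                 "mean_dice": similarity.mean_similarity(sim),
                 "n_pairs": len(sim.offdiagonal())}
            )
        mean_df = pd.DataFrame(mean_rows).sort_values(
            "mean_dice", ascending=False
        )
        mean_df.to_csv(out / "mean_similarity.tsv", sep="\t", index=False)
        report["mean_similarity"] = mean_df.to_dict(orient="records")
        _finish_stage(stage)

        stage = "prank"
        prank_results = []
        for sa, sb in itertools.combinations(sims, 2):
            res = prank.prank_score(
                sims[sa], sims[sb],
                cutoff=config.cutoff, quantile=config.cutoff_quantile,
            )
            prank_results.append(res.to_dict())
        with open(out / "prank.json", "w") as fh:
            json.dump(prank_results, fh, indent=2)
        report["prank"] = prank_results
        _finish_stage(stage)

        if chem is not None:
            stage = "chemical_correlation"
            chem_rows = []
            for system, sim in sims.items():
                try:
                    r, n_pairs = similarity.chem_tgx_correlation(sim, chem)
                    chem_rows.append(
                        {"system_id": system, "pearson_r": r, "n_pairs": n_pairs}
                    )
                except ValueError as exc:
                    logger.warning("chemical correlation for %s: %s", system, exc)
            pd.DataFrame(chem_rows).to_csv(
                out / "chem_correlation.tsv", sep="\t", index=False
            )
            report["chem_correlation"] = chem_rows
            _finish_stage(stage)

        if annotations is not None:
            stage = "stability"
            table = stability.stability_table(
                list(sims.values()), annotations, min_members=config.min_members
            )
            table.to_csv(out / "stability.tsv", sep="\t", index=False)
            report["stability"] = table.to_dict(orient="records")
            _finish_stage(stage)

        if gene_sets is not None:
            stage = "enrichment"
            rankings = {}
            for system, matrix in matrices.items():
                res = enrichment.enrich_system(
                    matrix, gene_sets, k=config.k, alpha=config.alpha
                )
                res.table.to_csv(
                    out / f"{system}.enrichment.tsv", sep="\t", index=False
                )
                res.ranking.to_frame().to_csv(
                    out / f"{system}.pathway_ranking.tsv", sep="\t", index=False
                )
                rankings[system] = res.ranking
            pop_summaries = []
            for sa, sb in itertools.combinations(rankings, 2):
                curve = enrichment.pop(
                    rankings[sa], rankings[sb],
                    range(config.L_min, config.L_max + 1),
                )
                curve.to_frame().to_csv(
                    out / f"pop.{sa}.{sb}.tsv", sep="\t", index=False
                )
                pop_summaries.append(
                    {"system_a": sa, "system_b": sb,
                     "mean_pop": curve.summary,
                     "n_L": len(curve.L_values)}
                )
            with open(out / "pop_summary.json", "w") as fh:
                json.dump(pop_summaries, fh, indent=2)
            report["pop"] = pop_summaries
            _finish_stage(stage)

            stage = "geneset_prank"
            gs_results = prank.prank_by_geneset(
                list(matrices.values()), gene_sets,
                fc_threshold=config.fc_threshold,
                cutoff=config.cutoff, quantile=config.cutoff_quantile,
            )
            prank.geneset_prank_table(gs_results).to_csv(
                out / "geneset_prank.tsv", sep="\t", index=False
            )
            overlap = prank.top_pathway_overlap(
                gs_results, top_n=config.top_n_pathways
            )
            overlap_json = {
                " & ".join(sorted("-".join(p) for p in combo)): sorted(region)
                for combo, region in overlap.items()
            }
            with open(out / "top_pathway_overlap.json", "w") as fh:
                json.dump(overlap_json, fh, indent=2)
            report["top_pathway_overlap"] = overlap_json
            _finish_stage(stage)

        if config.conditions:
            stage = "condition_sweep"
            grids = {}
            for label, paths in config.conditions.items():
                dose, _, time = label.partition("|")
                cond_matrices = _load_matrices(
                    paths, config.scale, (dose, time)
                )
                grids[(dose, time)] = {
                    system: similarity.pairwise_similarity(
                        make_signatures(m, k=config.k), system
                    )
                    for system, m in cond_matrices.items()
                }
            sweep = prank.condition_sweep(
                grids, cutoff=config.cutoff, quantile=config.cutoff_quantile
            )
            sweep.to_csv(out / "condition_sweep.tsv", sep="\t", index=False)
            report["condition_sweep_rows"] = len(sweep)
            _finish_stage(stage)

    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    manifest["complete"] = True
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
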
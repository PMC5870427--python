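# pranktgx

Concordance analysis of preclinical toxicogenomic (TGx) assay systems.

Toxicology programs routinely profile the same compounds in several test
systems — e.g. primary rat hepatocytes in vitro, a single-dose 24 h rat study,
and a 28-day repeat-dose rat study — and need to know how far the cheaper,
faster systems can stand in for the expensive ones. `pranktgx` answers that
question from gene-expression fold-change data alone, for users doing
in vitro to in vivo extrapolation (IVIVE), read-across, or assay selection.

## What it computes

**Directional signatures.** For each compound, the top and bottom k genes
ranked by log2 fold change (default k = 200, a 400-gene signature), or, when
restricted to a pathway gene set, all genes with |fold change| > 1.5.

**Direction-aware Dice similarity.** For compounds *i*, *j* with shared
up-regulated gene count N<sub>i,j,up</sub> and shared down-regulated count
N<sub>i,j,down</sub>:

```
Dice(i, j) = 2 (N_i,j,up + N_i,j,down) / (400 + 400)   [top-200 signatures]
```

Genes moving in opposite directions contribute nothing. Threshold-mode
signatures use the generalized denominator (the sum of the four set sizes).

**PRank concordance.** Pairs that look similar in one system (Dice above a
cutoff — fixed 0.4 by default, or a quantile of the system's own values) are
taken as positives; the other system's similarities are scored by ROC-AUC
(Mann–Whitney rank formulation). Both label/score directions are averaged
into a symmetric PRank score in [0, 1].

**Therapeutic-category stability.** For each ATC level-2 category with ≥ 5
compounds, the ratio of mean within-category Dice to mean across-category
Dice; ratios above 1 mean the assay discriminates that drug class.

**Pathway-level concordance.** Per-compound over-representation analysis of
signatures against pathway gene sets (one-sided hypergeometric test,
Benjamini–Hochberg adjusted per compound, α = 0.05), pathways ranked by
perturbation frequency, and the percentage of overlapping pathways
POP(L) = |top-L(A) ∩ top-L(B)| / L over L = 5..60.

**Synthetic multi-system generator.** A seeded generator of fold-change
matrices for several systems observing shared latent compound effects at
configurable pairwise correlations, with planted therapeutic categories and
pathway perturbations — so every stage of the pipeline runs and is testable
with no external download.

## Worked example

```python
import itertools
import pranktgx as px
from pranktgx.simulate import SyntheticConfig, generate

bundle = generate(SyntheticConfig(seed=0))          # 3 systems, 5000 genes, 60 compounds
sims = {
    system: px.pairwise_similarity(px.make_signatures(matrix, k=200), system)
    for system, matrix in bundle.matrices.items()
}
for system, sim in sims.items():
    print(f"{system}: mean pairwise Dice = {px.mean_similarity(sim):.3f}")
for sa, sb in itertools.combinations(sims, 2):
    res = px.prank_score(sims[sa], sims[sb], quantile=0.95)
    print(f"PRank({sa}, {sb}) = {res.prank_score:.3f}")
```

prints

```
InVitro: mean pairwise Dice = 0.057
InVivo_S: mean pairwise Dice = 0.045
InVivo_R: mean pairwise Dice = 0.047
PRank(InVitro, InVivo_S) = 0.821
PRank(InVitro, InVivo_R) = 0.855
PRank(InVivo_S, InVivo_R) = 0.931
```

The low mean Dice values say each system resolves compound pairs well (most
pairs share few signature genes). The PRank ordering recovers the generator's
ground truth: the two in vivo designs were simulated with latent-signal
correlation 0.9, in vitro vs. repeat-dose at 0.7, in vitro vs. single-dose at
0.55 — so the single-dose study is the better surrogate for the 28-day study
than the in vitro assay is for either.

Stability ratios on the same bundle (`px.stability_table(...)`) show the
planted categories (category weight α = 0.7 / 0.6 / 0.5) at ratios ≈ 10 / 8 /
7 in the repeat-dose system, while the α = 0 category sits near 1 — an
undiscriminated drug class.

## Command line

```bash
prank simulate --out-dir sim/                      # synthetic bundle as TSV/GMT
prank score --system-a sim/InVitro.fc.tsv --system-b sim/InVivo_R.fc.tsv \
      --cutoff-quantile 0.95 --out score.json
prank run-all --config run.yaml                    # full report
```

Subcommands: `simulate`, `signatures`, `similarity`, `score`, `stability`,
`enrich`, `pop`, `run-all`. Inputs are plain text: fold-change TSV (genes ×
compounds), GMT gene sets, two-column homology maps, `compound<TAB>codes`
annotations.

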
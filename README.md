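# ccckit

Inference and evaluation of **cell-cell communication (CCC)** from
cluster-annotated single-cell RNA-seq data.

Cells coordinate through ligand-receptor signalling: a *source* cluster
expresses a transmitter protein, a *target* cluster the matching receiver.
Many scoring systems exist for prioritising such interactions, and they
disagree substantially. `ccckit` implements six of them behind one
interface, aggregates their rankings into a consensus, and provides the
evaluation machinery to compare methods and prior-knowledge resources:
top-k overlap, robustness to noise, and agreement with cytokine
activities, spatial colocalization and receptor protein abundance.

It is aimed at computational biologists who want to run several CCC scoring
systems on one dataset with one resource format, and at method developers
who need a benchmarking harness with planted ground truth.

## The scores

For ligand *l* in source cluster *s* and receptor *r* in target cluster *t*
(cluster means on the log-normalized layer; heteromeric complexes reduced to
their minimally expressed subunit; both entities required in ≥ 10% of
cells):

| method | magnitude | specificity |
|---|---|---|
| `cellphonedb` | (lₛ + rₜ)/2 | 1 − p, with p the one-sided empirical p-value over 1000 cluster-label permutations |
| `connectome` | lₛ · rₜ | (z(lₛ) + z(rₜ))/2 over DE genes (Wilcoxon p ≤ 0.05) |
| `natmi` | lₛ · rₜ | (lₛ/Σ_c l_c) · (rₜ/Σ_c r_c) |
| `sca` | LRscore = √(lₛrₜ)/(μ + √(lₛrₜ)) | — |
| `logfc` | (log2FC(l,s) + log2FC(r,t))/2 | same |
| `crosstalk` | minmax(PEM) · minmax(NST) | same |

The consensus uses robust rank aggregation: for sorted normalized ranks
r₍₁₎ ≤ … ≤ r₍K₎ across the K methods (missing predictions imputed at rank
1), ρ = min_k BetaCDF(r₍k₎; k, K−k+1) and the consensus score is
min(ρ·K, 1) — small when an interaction is consistently near the top of
several rankings. See `docs/methods.md` for the full definitions and
numerical conventions.

## Worked example

```python
import ccckit

cfg = ccckit.ScenarioConfig(seed=1)            # 20 clusters x 100 cells, 2000 genes
dataset, truth = ccckit.generate_dataset(cfg)  # 20 planted ligand-receptor pairs
resource = ccckit.generate_resource(cfg, truth)  # planted + 300 decoy interactions

scored = ccckit.score_methods(dataset, resource, "all",
                              ccckit.MethodConfig(seed=1))
long = ccckit.add_consensus(scored)

from ccckit.consensus import rank_interactions
top = rank_interactions(long, "consensus").head(3)
print(top[["source", "target", "ligand_complex", "receptor_complex",
           "score_specificity"]].to_string(index=False))
```

```
source target ligand_complex receptor_complex  score_specificity
   C08    C18          G0017            G0018                1.0
   C15    C05          G0033            G0034                1.0
   C11    C01          G0023            G0024                1.0
```

The top consensus interactions are planted pairs: ligand `G0017` was
upregulated in its source cluster `C08` and receptor `G0018` in target
`C18`, and every scoring system ranks the pair near the top, so its
aggregated rank probability ρ is essentially zero (specificity
= 1 − min(ρ·K, 1) ≈ 1).

The same pipeline is available from the shell:

```bash
ccckit simulate --seed 1 --out sim/
ccckit score --expression sim/expression --resource sim/resource.csv \
       --seed 1 --out scores.tsv
ccckit consensus --scores scores.tsv --out consensus.tsv
ccckit overlap --scores consensus.tsv --top-k 1000 --out jaccard.tsv
```

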
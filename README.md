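# netwfdr

Network-weighted false discovery rate control for gene-level hypothesis
tests.

## The problem

Genome-scale experiments test tens of thousands of genes at once. The
Benjamini–Hochberg (BH) step-up controls the false discovery rate (FDR) but
treats every gene identically, ignoring the large body of prior biological
knowledge encoded in functional gene networks — graphs whose edge scores are
posterior probabilities that two genes act in the same process or pathway.

`netwfdr` implements a weighted FDR procedure that turns network
connectivity around a small set of user-chosen seed genes into per-gene
p-value weights. Genovese-style weighted BH keeps FDR control for *any*
nonnegative weights `W_i` with

```
sum_{i=1}^m W_i = m,
```

where `m` is the number of tests: the procedure applies ordinary BH to the
weighted p-values `Q_i = min(P_i / W_i, 1)`. The weights themselves come
from the network:

1. extract the subnetwork of genes within one hop of the seed genes
   (edge-confidence threshold and hop count are configurable);
2. for each gene compute the **total relationship confidence** (TRC), the
   sum of the confidences of its incident edges in that subnetwork;
3. variance-stabilise with `log(1 + TRC)` (hub genes can have TRCs orders of
   magnitude above the median);
4. divide by the mean over the testing universe, so the weights have mean 1
   and sum `m`.

Genes connected to the seed neighbourhood are up-weighted (easier to
detect); genes with no network support get weight 0 and can never be
rejected. A **sensitivity variant** guards against seed-selection bias by
pinning the seed genes' own weights to 1 and redistributing the freed mass
over the remaining genes.

The package also ships a hypergeometric over-representation module (GMT
gene-set collections, one-sided Fisher exact upper tail) and a Monte-Carlo
simulation harness that checks the two statistical claims that make the
method worth using: empirical FDR at or below the nominal level, and a power
gain when the weights are informative.

## Worked example

```python
>>> import pandas as pd
>>> from netwfdr import (FunctionalNetwork, QuerySet, assign_weights,
...                      weighted_bh)
>>> net = FunctionalNetwork.from_edges(
...     [("q", "a", 0.5), ("q", "b", 0.2), ("a", "c", 0.4), ("d", "e", 0.9)])
>>> genes = list("qabcde")
>>> w = assign_weights(net, QuerySet.from_iterable(["q"]), genes,
...                    scheme="raw", expansion=2)
>>> {g: round(w[g], 3) for g in genes}
{'q': 1.909, 'a': 2.455, 'b': 0.545, 'c': 1.091, 'd': 0.0, 'e': 0.0}
>>> pvals = pd.DataFrame({"gene_id": genes,
...                       "p_value": [0.001, 0.02, 0.9, 0.105, 0.5, 0.6]})
>>> res = weighted_bh(pvals, w, level=0.2)
>>> res.n_rejected, res.rejected_genes()
(3, ['q', 'a', 'c'])
```

The weights sum to `m = 6`: the four genes in the 2-hop seed subnetwork
share the whole weight mass in proportion to their TRC, while `d` and `e`
(disconnected from the seed) get weight 0 — their weighted p-values are
capped at 1 and they can never be rejected. At level 0.2 the weighted
procedure rejects `q`, `a` and `c`; plain BH on the same p-values
(`bh_stepup(pvals["p_value"], 0.2)`) rejects only `q` and `a`: the network
support of `c` (weight 1.09, weighted p = 0.105 / 1.09 = 0.096) is what
pushes it over the line.

The same pipeline is available from the shell:

```bash
netwfdr weights --network edges.tsv --queries seeds.txt \
    --universe pvalues.tsv --scheme log1p -o weights.tsv
netwfdr adjust --pvalues pvalues.tsv --weights weights.tsv --level 0.2
netwfdr enrich --query hits.txt --gmt pathways.gmt
netwfdr simulate --m 2000 --reps 500 --seed 7
```

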
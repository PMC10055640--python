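# bsp-spatial

Detection of **spatially variable genes (SVGs)** in 2D and 3D spatially
resolved transcriptomics, using the **big-small patch (BSP)** statistic — a
non-parametric, dimension-agnostic variance-ratio test — together with a
Moran's I baseline, labeled 2D/3D benchmark simulators, and power-vs-FDR
evaluation utilities.

## Who this is for

Computational biologists analysing spot- or cell-resolved expression data
(Visium-style arrays, seqFISH/MERFISH segmentations, stacked serial sections)
who want to rank genes by the strength of their spatial expression pattern
without assuming a kernel, a parametric spatial covariance, or a fixed
dimensionality.

## The statistic

Let `X_i(j)` be the expression of gene *j* at spot *i* (min-max normalized to
[0, 1] per gene), with spot coordinates rescaled by the spot density
`s = (M / V)^(1/d)` so that the typical spot spacing is about one unit. For a
radius *D*, the *patch* of spot *i* is the set of spots within Euclidean
distance *D*, and the *local mean* `X̂_i(j)` is the average of gene *j* over
that patch. Write

    σ_D(j) = var_i( X̂_i(j) )

for the variance of the local means. At a small radius `D1` (default 1 unit)
σ captures noise plus signal; at a big radius `D2` (default 3 units) only
coherent spatial structure survives the smoothing. After normalizing each
granularity by its maximum over genes, the BSP score is the ratio

    r(j) = ( σ_D2(j) / max_j σ_D2 ) / ( σ_D1(j) / max_j σ_D1 ).

Genes with a genuine spatial pattern keep a large σ_D2 relative to σ_D1 and
score high. A beta distribution is fit to the score population by maximum
likelihood (on permutation-null genes generated on the fly when the panel is
small), and each gene's p-value is the upper-tail probability of its score.
Because only Euclidean distances enter, the same code handles 2D arrays and
3D stacked sections.

## Worked example

```python
import numpy as np
from bsp import Sim2DConfig, simulate_replicate_2d, run_bsp, power_at_fdr

rep = simulate_replicate_2d(Sim2DConfig(n_svg=100, n_null=900,
                                        fold_change=4.0, tau=0.5, seed=11))
table = run_bsp(rep.dataset)
print(table.head(5).round(4).to_string(index=False))
```

```
  gene_id  sigma_D1  sigma_D2  weight  score  p_value  p_adjusted  is_svg
svg_00000    0.0113    0.0057  0.5661 0.9535   0.0052      0.1111    True
svg_00001    0.0109    0.0052  0.4819 0.8889   0.0146      0.2054    True
svg_00002    0.0126    0.0073  0.6775 1.0887   0.0000      0.0026    True
svg_00003    0.0055    0.0030  0.2920 1.0054   0.0015      0.0544    True
svg_00004    0.0138    0.0072  0.5330 0.9733   0.0035      0.0936    True
```

The replicate contains 100 genes with a fold-change-4 hotspot pattern on 260
spots plus 900 spatially random permutation genes. `run_bsp` calls 97 genes
at raw p < 0.05, all 97 of them true SVGs, and

```python
power_at_fdr(table.p_value.to_numpy(), rep.is_svg_truth, [0.05]).tpr
# array([1.])
```

shows full power at a realized false discovery rate of 0.05: the small-patch
variance `sigma_D1` and big-patch variance `sigma_D2` shrink together for
patterned genes but σ_D2 collapses for permuted ones, so the ratio separates
the classes cleanly.

The same pipeline runs from the shell:

```bash
bsp simulate --mode 3d --pattern I --r 2.0 --quantile 0.8 --sigma 1 --seed 7 --out-dir rep/
bsp run --expr rep/expression.tsv --coords rep/coords.tsv --out results.tsv
bsp evaluate --results results.tsv --truth rep/truth.tsv --out curve.tsv
```

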
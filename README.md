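# scbn — scale-based normalization for cross-species RNA-seq

Comparing gene expression **between two species** (say, human and mouse) is
harder than comparing samples of one species: the orthologous genes have
different lengths, the libraries have different sequencing depths, and part
of each genome has no counterpart in the other. Before any differential
expression (DE) call can be trusted, the two libraries must be placed on a
common scale.

`scbn` implements a scale-based normalization method for this setting,
together with the exact test it calibrates, a faithful synthetic-data
generator, and the benchmark metrics used to evaluate it.

## Model and method

For one-to-one orthologous gene *g* in species *t* ∈ {1, 2}, the read count
X<sub>gt</sub> is Poisson with mean

    E(X_gt) = mu_gt · L_gt / S_t · N_t,     S_t = Σ_g mu_gt · L_gt,

where mu<sub>gt</sub> is the true expression level, L<sub>gt</sub> the gene
(transcript) length, N<sub>t</sub> the total orthologous read count, and
S<sub>t</sub> the species' total expression output. Equal expression
(mu<sub>g1</sub> = mu<sub>g2</sub>) is tested conditionally on the pair
total n<sub>g</sub> = x<sub>g1</sub> + x<sub>g2</sub>: under the null,
X<sub>g1</sub> | n<sub>g</sub> ~ Binomial(n<sub>g</sub>, p<sub>0</sub>) with

    p0 = c·L_g1·N_1 / (L_g2·N_2 + c·L_g1·N_1),

a SAGE-style exact test adjusted for lengths and depths. Everything hinges
on the scaling factor **c = S₂/S₁**, which is not observable directly.

`scbn` estimates c from a set *H* of *m* conserved orthologous genes assumed
non-DE (the cross-species analogue of housekeeping genes): at the right c
their p-values are (near-)uniform, so the empirical type-I error at level α
should equal α. The estimator minimizes

    c_opt = argmin_{c>0} | (1/m) Σ_{g∈H} I(p_g(c) < α) − α |

by a two-stage grid search (coarse log-spaced pass, linear refinement).
Because the exact test is discrete — hence conservative — the rejection rate
can dip *below* α around the true c; the estimator recognises that dip and
returns its geometric midpoint. A median-ratio baseline (`MedianNormalizer`:
median of length/depth-adjusted expression ratios over the interquartile
range of the conserved set) is included for comparison, along with a plug-in
positive-FDR (pFDR) estimator.

## Worked example

```python
from scbn import (SimConfig, simulate_dataset, SCBNNormalizer,
                  MedianNormalizer, test_all, prf_metrics)

cfg = SimConfig(prop_de=0.1, fold=1.5, noise_rate=0.3, seed=42)
table, conserved, truth = simulate_dataset(cfg)

scbn = SCBNNormalizer(alpha=0.05).fit(table, conserved)
med = MedianNormalizer().fit(table, conserved)
pv = test_all(table, scbn.scaling_factor_).pvalues
```

prints (via the accompanying report lines):

```
simulated 13000 ortholog pairs, true c = S2/S1 = 2.130
SCBN estimate:   c = 2.106 (objective 0.1870, plateau [2.105, 2.106])
median estimate: c = 2.048
  scbn: 3471 DE calls, precision 0.876, sensitivity 0.612
median: 3663 DE calls, precision 0.661, sensitivity 0.588
```

The dataset has 10% DE genes at 1.5-fold and a conserved anchor set of 1000
genes of which 30% are secretly DE ("noise"). Despite the contamination the
calibrated estimate (2.106) stays within ~1% of the true factor (2.130),
while the median baseline is dragged toward the contaminants; at a p < 0.01
cutoff this translates into a visibly better precision among the DE calls
(unique genes — expressed in one species only — are excluded from the
precision accounting, as they are detected trivially).

A command-line interface mirrors the library (`scbn simulate`,
`scbn normalize`, `scbn test`, `scbn evaluate`, `scbn study`); run
`scbn --help` for details.

## Real data

The human/mouse study that motivates the package can be re-analysed with
`scbn.evaluation.real_data_summary` given the study's supplementary
ortholog table and conserved-transcript lists; `tests/test_real_data.py`
documents the expected files and runs only when they are present.
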
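# spex

Gene-expression prediction from chromatin features, extended with
protein-mediated spatial chromatin contacts.

Sequence- and chromatin-based expression predictors in the ExPecto family
summarise predicted epigenetic signal in a ±20 kb window around a gene's
transcription start site (TSS) and regress expression on those summaries.
That window misses a well-documented regulatory channel: enhancers tens of
kilobases to megabases away that are brought next to the promoter by
cohesin-, CTCF- or RNA-polymerase-II-mediated chromatin loops. `spex`
implements the spatial extension of that architecture: per-gene tensors gain
one extra column that sums predicted chromatin signal over contact-map bins
looping to the TSS, and the package includes the full evaluation apparatus —
repeated training with Welch/Bonferroni significance testing, residual
diagnostics with a best-across-factors construction and a 0.5-SD cutoff —
plus a synthetic-data generator so the whole pipeline is testable without
any external downloads.

It is aimed at computational/regulatory genomicists who want to quantify how
much ChIA-PET-style interaction maps add to chromatin-only expression
models, or to reuse the tensor/evaluation machinery with their own
predictors and contact data.

## The model

For gene *g* with TSS *t*, an epigenetic predictor scores the 200 bins of
200 bp tiling [*t* − 20 kb, *t* + 20 kb) for F features. Per feature, the
bins collapse into 10 positional summaries

&nbsp;&nbsp;&nbsp;&nbsp;x<sub>side,λ</sub> = Σ<sub>d</sub> e<sup>−λ·d</sup> · s(d),&nbsp;&nbsp; side ∈ {upstream, downstream}, λ ∈ {0.01, 0.02, 0.05, 0.1, 0.2} per bin,

where *d* is the bin's distance from the TSS in bins and upstream/downstream
are oriented by strand — the F×10 **linear tensor**. The **spatial column**
adds, per feature, the summed predicted signal over every contact-matrix bin
*B* such that the pixel (TSS bin, *B*) has (balanced) count ≥ 0.5 and *B*
lies entirely outside the ±20 kb linear scope, each such bin tiled at 200 bp.
The F×11 (or F×10 baseline) tensor is flattened and fed to gradient-boosted
regression trees (XGBoost, squared-error objective, histogram method)
predicting log₁₀(expression + 10⁻⁴); models are scored by Spearman rank
correlation on genes from a held-out chromosome (chr8 by default).

To decide whether the spatial column helps, both arms are retrained *n*
times (each run a seeded Monte-Carlo subsample of the training genes) and
the score distributions compared with Welch's unequal-variance t-test,
Bonferroni-corrected across the comparisons made; per-gene residuals
(observed − predicted) across factor-specific models yield the
"best-residual" distribution whose 0.5-SD symmetric cutoff classifies genes
as well-predicted by the spatial models, the baseline, or both.

## Worked example

```bash
python examples/03_train_and_score.py
```

```
baseline (F×10): test Spearman = 0.484 (225 train, 75 test genes)
spatial (F×11): test Spearman = 0.978 (225 train, 75 test genes)
```

On the packaged synthetic conditions — 300 genes, 8 features, 60% of genes
looped to a distal enhancer whose signal feeds their expression — the
chromatin-only baseline explains the promoter-driven part of expression
(ρ ≈ 0.48) while the spatial model also sees the enhancer signal through the
contact map and nearly saturates (ρ ≈ 0.98). The repeated-training
comparison (`examples/04_repeated_comparison.py`) prints

```
 distal-effect: baseline 0.416 → spatial 0.969  (Δ +0.5528, p_raw 6.61e-24, p_adj 1.32e-23)
          null: baseline 0.949 → spatial 0.952  (Δ +0.0036, p_raw 2.65e-01, p_adj 5.29e-01)
```

i.e. the improvement is highly significant when the loops are informative
and statistically absent under matched null conditions where the same loops
carry no expression signal. `examples/05_residual_analysis.py` runs the
residual/cutoff analysis across three factor-specific contact maps.

A thin CLI mirrors the library (`spex simulate`, `spex build-tensors`,
`spex train`, `spex compare`, `spex residuals`); see `--help` on each.

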
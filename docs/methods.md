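# Methods

## Coordinates and formats

All coordinates are 0-based, half-open. GTF input (1-based, closed) is
converted on read: the TSS of a `+` feature is `start − 1`, of a `−` feature
`end − 1`. Contact matrices follow the cooler schema (chroms/bins/pixels
tables, optional per-bin `weight` column, multi-resolution files under
`/resolutions/<r>`), read and written directly through HDF5; a 7-column
whitespace pixel list (`chrom1 start1 end1 chrom2 start2 end2 count`) is
accepted as a text dialect. Multi-resolution files require an explicit
resolution — there is no silent default. When balancing weights are present
the stored counts are `raw × w_i × w_j` (bins with NaN weight dropped) and
the matrix is flagged `balanced`; `raw_counts=True` overrides. The 0.5 loop
filter applies to the counts as stored, i.e. to balanced counts when weights
exist: a 0.5 threshold is only meaningful on a normalised scale. Only
intra-chromosomal pixels are kept — ChIA-PET loop calls are overwhelmingly
intra-chromosomal and the spatial selection never crosses chromosomes.

## The linear tensor

The ±20 kb TSS window is tiled into 200-bp bins (200 bins). The two bins
adjacent to the TSS sit at distance 0 on their side; a bin at distance *d*
(in bins) contributes weight e^(−λ·d) to its side's summary at decay rate λ.
Rates default to {0.01, 0.02, 0.05, 0.1, 0.2} per bin — the positional
transformation of the released ExPecto feature reduction — and are
configurable. Columns are ordered upstream λ₁..λ₅ then downstream λ₁..λ₅,
with upstream/downstream oriented by gene strand, so a minus-strand gene's
tensor equals the plus-strand tensor of the mirror-reflected signal. Windows
that run off a chromosome end are zero-padded (out-of-range positions
contribute zero signal), not dropped.

## The spatial column

For the bin T containing the TSS (the binned representation of
"(TSS, TSS + resolution)"; sub-bin anchor positions are not representable in
a binned matrix), every pixel (T, B, c) qualifies when c ≥ 0.5 and B's
interval does not overlap [TSS − 20 kb, TSS + 20 kb). Overlap-based
exclusion (rather than midpoint distance) is deliberately conservative: a
bin partially inside the window is already partly covered by the linear
tensor, and counting it again would double-book that signal. Qualifying bins
are tiled at 200 bp, the predictor is evaluated per tile, and everything is
summed per feature into one F×1 column — summing rather than averaging keeps
the tensor a fixed size while letting the column scale with the total
contacted territory (the alternative, per-region normalisation, would erase
the distinction between one and many enhancers). A gene with no qualifying
contact, or whose chromosome is missing from the matrix, gets a zero column
(the latter with a warning), so the F×11 shape is uniform across genes.

## The predictor contract

Downstream code assumes only `n_features` and
`predict_window(chrom, start, end) → (F,)`. The packaged `TrackPredictor`
returns per-feature mean signal over the window from run-length-encoded
ground-truth tracks (O(log n) per query via precomputed cumulative
integrals). Returning means rather than sums makes the output independent of
how a region is tiled; all summation happens in the spatial column where it
is specified. The predictor is strand-agnostic; orientation is applied in
the tensor builder. A trained CNN scoring 2002 chromatin features would slot
into the same contract; everything downstream is F-generic and the tests run
at F = 8.

## Regression model

Gradient-boosted regression trees (XGBoost `gbtree`, `reg:squarederror`,
histogram tree method) on row-major (feature-major) flattened tensors;
targets are log₁₀(expression + 10⁻⁴) — the pseudocount is configurable.
Defaults: learning rate 0.1, max depth 4, 150 rounds, subsample 0.8. These
are sized for training sets of a few hundred genes: deeper/longer fits add
nothing on design matrices this small but slow the repeated-training
protocol roughly tenfold and overfit the handful of irrelevant columns more.
The GPU histogram method is a config switch (`tree_method`), not a default,
so results are hardware-independent.

## Repeated training and significance

Each experiment retrains both arms (F×10 baseline, F×11 spatial) `n_runs`
times; run *i* uses seed `base_seed + i` in both arms. A run is a
Monte-Carlo cross-validation replicate: a seeded random 50% subset of the
training genes is drawn (the same subset in both arms) and both fits are
scored on the full held-out chromosome. This is the run-level stochasticity
that makes a score *distribution* meaningful — a deterministic CPU fit
repeated n times would yield n copies of one number and a degenerate test —
and its magnitude (per-run score SD ≈ 0.5–1.5 × 10⁻²) matches what
large-scale repeated-training protocols of this kind exhibit. Arms are
compared with Welch's unequal-variance two-sided t-test (implemented from
the closed-form statistic and Welch–Satterthwaite degrees of freedom; two
zero-variance arms with equal means give p = 1 by convention, any other
zero-variance input is an error). Bonferroni correction multiplies each raw
p by the number of comparisons in the invocation, capped at 1. Experiments
can be pooled by mediating factor and overall; the improvement direction is
reported as a mean difference separately from the two-sided p.

## Residual analysis

Residuals are observed − predicted log-expression on the held-out genes.
Across factor-specific models, the per-gene residual of smallest magnitude
is the best residual (ties go to the first label in the configured factor
order and are flagged). The cutoff interval is [−h, +h] with
h = k × sample SD (ddof = 1) of the best residuals, k = 0.5 by default. The
interval is centred at zero, not at the empirical mean — the quantity being
thresholded is distance from a perfect prediction. Genes are classified by
interval membership under the best-factor and baseline residuals into
both / spatial-only / baseline-only; the counts satisfy
`both + spatial_only = within_spatial` and
`both + baseline_only = within_baseline` by construction. Normality of a
residual vector is checked with the Anderson–Darling test for the normal
family with estimated parameters (SciPy), reported against the standard
15/10/5/2.5/1% critical values.

## Synthetic data

The generator emulates the mechanism the spatial column targets. Per
configuration (defaults in parentheses, used by the frozen fixtures):
genes (300) spread over chromosomes (4 × 8 Mb, chr1–3 + held-out chr8) at
≥ 40 kb spacing; promoter signal of amplitude U(1, 5) on features 0..F/2−1
over ±1 kb of the TSS; a fraction (0.6) of genes looped to a distal enhancer
bin (> 20 kb + 1 bin, < 2 Mb from the TSS; resolution 5 kb) carrying
amplitude U(1, 5) on features F/2..F−1 and a contact count U(0.6, 5).
Expression is `local_effect·promoter + distal_effect·enhancer·has_distal +
N(0, noise_sd)` clipped at zero (local_effect 1, distal_effect 1, noise_sd
0.25 — amplitudes ≥ 1 keep the clipping rate negligible). Threshold
behaviour is exercised deliberately: sub-threshold TSS loops (rate 0.3,
count U(0.05, 0.45), with decoy enhancer signal) and decoy loops touching no
TSS bin (0.5 per gene) are added and must never be selected. The null
fixture is identical except `distal_effect = 0`: the loops exist but carry
no expression information. Enhancer bins avoid all TSS bins so loop anchors
stay unambiguous; two genes' enhancers may coincide, in which case their
track signal adds (a mild, realistic cross-talk). `split_contacts_by_factor`
partitions one contact map into per-factor maps for the residual analysis,
emulating separate protein-mediated interaction datasets over one genome.

Not emulated: Hi-C distance-decay background, sequence-level signal,
overlapping genes/isoforms, multi-tissue expression panels, and real
predictor noise (the track predictor recovers ground truth exactly). Passing
tests therefore demonstrate the machinery — selection, aggregation, the
statistics — under a favourable signal-to-noise regime, not performance on
real chromatin data.

## Problem sizes and determinism

The packaged studies use 300 genes × 8 features, 25 training repetitions per
arm, and a 75-gene held-out set — sizes at which the full pipeline (simulate
→ tensors → repeated training → residual analysis) completes in seconds to a
couple of minutes on one CPU while leaving the comparison well-powered. All
randomness flows from explicit integer seeds (NumPy `default_rng`, XGBoost
`seed`); identical seeds reproduce outputs byte-for-byte, including written
files. The tensor cache stores raw row-major float64 plus a JSON sidecar
recording shape, flattening order and build parameters, and verifies the
sidecar against the file on load.

## Known limitations

The spatial column is a single summed feature: it cannot distinguish many
weak from few strong contacts, encodes no contact distance, and inherits any
bias of the upstream predictor at distal sites. The loop filter trusts the
contact map's normalisation (0.5 is scale-dependent). The repeated-training
arms share per-run subsets (paired), while Welch's test treats them as
independent samples — conservative for detecting improvements under positive
pairing correlation. Factor maps produced by random pixel-splitting share a
genome-wide loop budget, unlike real per-protein ChIA-PET libraries whose
loop sets overlap substantially.
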
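# Methods

## Problem and model

`stloc` treats spatial origin recovery as supervised regression: a
spatial-transcriptomics (ST) reference provides (expression, position)
pairs, and a fully connected network learns the map from a cell's
transcriptome to its min–max-normalized coordinates. The assumptions are
those of any such regression: expression varies smoothly enough with
position that a transcriptome constrains location; the query cells come
from the same tissue (or a batch-comparable one, see gene filtering); and
the reference sampling covers the domain the query cells originate from.
Nothing in the model distinguishes assay chemistry — image-based and
sequencing-based references differ only in scale and noise.

### Preprocessing

Counts are depth-normalized to 10,000 per observation and transformed with
ln(1+x) — the single-cell community standard; the natural log is used
throughout. Coordinates are normalized per axis to [0, 1] by min–max;
a polar option converts (x, y) to (radius, angle in (−π, π]) about the
centroid of the training positions before min–max (useful for circular
sections; both derived axes are normalized uniformly). A coordinate axis
with zero range is an error, not a silent pass-through. Out-of-range
points map linearly outside [0, 1]; the normalizer never clips —
predictions far from every bead are simply reported as unassigned at the
mapping stage.

### Network and loss

Default architecture: input (one node per gene) → hidden widths 4096,
1024, 256, 64, 16, 4 → output of 2 (or 3) sigmoid units. Hidden layers use
ReLU; dropout at rate 0.05 is applied after activation on the input and
the first five hidden layers; prediction runs with dropout off, with an
opt-in Monte-Carlo mode that averages S stochastic passes. The loss is
RMSE over the batch plus an L1 penalty λ·Σ|W| over all dense weight
matrices (biases excluded), λ = 1e-8. Optimization is mini-batch Adam
(lr 0.001, β₁ 0.9, β₂ 0.999, ε 1e-7), Glorot-normal initialization, zero
biases, seeded per-epoch shuffling, learning rate halved after 20 epochs
without validation improvement down to 1e-5, early stopping after 50, and
at most 500 epochs by default. A random 10% validation split (seeded)
drives the schedule; the weights with the best validation loss are
restored at the end, and the validation split also supplies r̄, the mean
per-axis Pearson correlation between predictions and truth that scales
the normalized gene-importance scores.

Hidden pre-activations are batch-normalized (ε 1e-3, running-statistics
momentum 0.99, learned scale/shift; inference uses running statistics).
This is not cosmetic: without normalization the narrow tail of the funnel
(widths 16 and 4) can die completely early in training — the RMSE
gradient has near-constant magnitude, Adam's sign-following updates drift
every pre-activation in a 4-unit layer negative while the output chases
the coordinate mean, and once all units are off the gradient is exactly
zero and training is permanently stuck at a constant prediction. We
observed this collapse on roughly half of seeds at small scale.
Batch normalization re-centers the pre-activations each step and removes
the failure mode entirely; it can be disabled with
`ModelSpec(batch_norm=False)`.

Everything is implemented in numpy with analytic gradients (exposed via
`loss_and_grads` and verified against central finite differences in the
test suite, both with and without batch normalization). Training is
bit-reproducible for a fixed seed in single-threaded mode. Batch sizes
follow the dataset-size rule: 16 for very small references, 128 for
Visium-scale (thousands of spots), 4096 for large beads arrays; a batch
larger than the training set is clamped with a warning.

### Wasserstein gene filtering

When a query batch is mapped onto a reference, each shared gene's
empirical expression distributions (reference vs query, on the normalized
log scale — selection sits after normalization in the pipeline) are
compared by the 1D Wasserstein distance W₁ = ∫|U−V|; genes with W₁ ≥ 0.1
are dropped. A constant shift of c in log-expression moves W₁ by exactly
|c|, so additive batch effects are removed while sampling fluctuation
(which shrinks as n grows) is kept. Empirical CDFs weight each
observation 1/n; unequal sample sizes are handled by exact step-function
integration (scipy's implementation, cross-checked in the tests against
an explicit CDF integration oracle). Without a query set, selection is
skipped and all reference genes train the model.

### Fine mapping and reconstruction

Predicted unit coordinates are denormalized with the reference normalizer
so distances are in the reference's physical units (µm). Every cell
within a cutoff radius of a bead center joins that bead (defaults: 15 µm
for Slide-seqV2-like, 110 µm for Visium-like spacing, both treated as
radii); cells may join several beads, and cells far from every bead join
none (counted in the log). A bead's reconstructed expression is the
convex combination Σⱼ wⱼ·exprⱼ with wⱼ = (1/dⱼ)/Σᵢ(1/dᵢ). A cell exactly
at the center (d = 0) takes the limit: weight 1 (shared equally among
exact hits), avoiding an arbitrary epsilon. Empty beads carry NaN, never
zeros — a zero would be a fake measurement for downstream statistics.

### Consistency and benchmarking statistics

* **Pairwise Pearson r / pairwise RMSE** compare the vectors of all
  n(n−1)/2 inter-point distances (canonical i<j ordering) between true
  and predicted positions, both on the min–max-normalized scale; they are
  exactly invariant to rigid motions of either set, which is the right
  property for a mapping whose orientation is arbitrary.
* **Moran's I** (per gene) uses a binary symmetric k-nearest-neighbor
  graph, k = 6 — the common default in the single-cell ecosystem, and the
  implementation is cross-checked against scanpy's in the tests.
* **Bivariate Moran's I** between a gene's reference profile and its
  reconstruction uses inverse-distance weights 100/d for pairs closer
  than a threshold, 0 beyond. No canonical threshold exists for arbitrary
  geometries; the default is 2× the 95th percentile of nearest-neighbor
  distances (so nearly every observation keeps a handful of neighbors)
  and is logged prominently whenever used.
* Degenerate inputs (constant vectors, all-zero weight totals) raise
  typed errors instead of returning 0; a silent zero would corrupt gene
  rankings.

Fivefold cross-validation partitions observations disjointly (seeded),
trains a fresh model per fold, and reports per-fold and pooled metrics;
whether to average folds or pool their predictions is a reporting choice,
so both are returned. The coordinate normalizer is fitted once on the
full dataset so pooled predictions share a frame (only the coordinate
range crosses folds, not any expression information). An optional
bootstrap resamples observations with replacement (200 replicates by
default) for error bars.

### Gene-importance backtracking

Scores are computed backward from the output: for the last weight matrix,
S_I,j = Σₖ|W_I,j,k| (no mask); for each earlier matrix i,
S_i,j = Σₖ 1[S_{i+1,k} > Percentile(S_{i+1}, r)]·|W_i,j,k| with r = 50 by
default. Columns of Wᵢ and rows of Wᵢ₊₁ index the same hidden nodes, so
the mask gates matrix i's columns by matrix i+1's row scores. The
unmasked base case belongs to the *last* matrix: the recursion runs from
output to input and the returned scores are S₁ at the input — placing the
unmasked case at the input end would make the masks unreachable.
Percentiles interpolate linearly between order statistics (the midpoint
convention at r = 50), the comparison is strict, and all node scores —
including exact zeros — enter the percentile. Biases and batch-norm
parameters play no role. S₁ is finally rescaled to sum to r̄·Scaler
(Scaler = 1000), so models that localize better carry proportionally
larger scores; ranking ties break lexicographically by gene id for
determinism.

## The synthetic-tissue generator

The generator emulates what the method needs from real ST data: spots at
known positions (uniform-random, grid, or annulus layouts in a
1000×1000 µm box), a minority of genes with smooth spatial intensity
surfaces (linear gradients, Gaussian bumps, concentric rings, half-plane
steps — parameters recorded in a ground-truth sidecar), spatially flat
noise genes, negative-binomial counts (gamma–Poisson, size parameter
`dispersion`, default 10) and lognormal per-spot depth variation around
`mean_depth`. Pattern surfaces share one dynamic range (±75% around the
flat level) so SVG difficulty is governed by depth and dispersion, not by
amplitude differences. The query generator places new cells in the same
box, draws counts from the same surfaces, and returns depth-normalized
log expression with an optional additive batch shift on chosen genes —
applied on the normalized scale, where it is the exact translation the
Wasserstein filter targets. True query positions live only in the
ground-truth record, never in the expression container.

What passing on this data does *not* show: real tissues have correlated
cell-type domains, spatially varying capture efficiency, zero-inflation
beyond NB, segmentation errors and doublets, none of which are simulated.
The synthetic study demonstrates that the estimator and its statistics
are implemented correctly and can recover planted structure at realistic
depth and dispersion — not that any particular tissue is mappable.

## Default study conditions

The acceptance script and the heavier tests use one fixed study: 1500
spots × 150 genes, 40 spatially patterned, mean depth 2000 — a desk-scale
stand-in for a Visium-sized section — with hidden widths (256, 64, 16, 4),
batch size 128 (the dataset-size rule above), at most 150 epochs, and
fivefold cross-validation, against a label-permuted baseline with the
identical configuration. Under these conditions a run reports mean
pairwise r ≈ 0.94, an RMSE ratio to the permuted baseline ≈ 0.18, and SVG
AUROC ≈ 0.999 (seed-dependent in the second decimal).

## Known limitations

* Mapping accuracy is bounded by how informative expression is about
  position; regions of homogeneous expression collapse toward their
  centroid (visible as pairwise RMSE well above 0 even at high r).
* The importance scores have no null model; they rank genes but carry no
  significance statement.
* The sigmoid output confines predictions to the training bounding box —
  query cells from outside the reference domain cannot be extrapolated.
* Bead reconstruction is a weighted average, not a deconvolution; it does
  not attribute expression to cell types.
* No GPU path; the numpy implementation targets desk-scale data (up to
  ~10⁴–10⁵ observations) on one CPU.
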
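# stloc

Spatial-origin prediction for transcriptomes: learn where in a tissue a
transcriptome came from, directly from reference spatial-transcriptomics
(ST) data.

Sequencing-based ST assays (Visium, Slide-seqV2, Stereo-seq) measure gene
expression at barcoded positions; scRNA-seq measures richer transcriptomes
but loses position. `stloc` trains a fully connected network on an ST
reference to regress a cell's min–max-normalized spatial coordinates from
its log-normalized expression vector, then

* predicts spatial origins for query transcriptomes (held-out ST spots or
  scRNA-seq cells),
* reconstructs bead-level expression from the mapped cells by
  inverse-distance weighting, for visualization and consistency scoring,
* ranks spatially variable genes (SVGs) by backtracking the trained
  network's weight matrices.

It is aimed at computational biologists integrating scRNA-seq with ST
references, and ships a synthetic-tissue generator so the whole pipeline is
testable end to end without downloads.

## The model

With expression `x` (depth-normalized to 10,000 per cell, then ln(1+x))
and coordinates min–max normalized per axis to [0, 1], the regressor is an
8-layer network

    x → 4096 → 1024 → 256 → 64 → 16 → 4 → ŷ ∈ (0,1)^d

with ReLU hidden activations (batch-normalized), a sigmoid output, dropout
0.05 on the input and first five hidden layers, trained with Adam
(lr 0.001) on

    loss = RMSE(y, ŷ) + λ Σᵢⱼₖ |W_ijk|,      λ = 1e-8 by default,

where RMSE = √(Σₜ‖yₜ−ŷₜ‖²/N). The L1 penalty shrinks weights that do not
help localization, so the surviving weights are interpretable: gene j's
importance S₁ⱼ is computed by walking the weight matrices backward from the
output, at each step summing |W| over only those downstream nodes scoring
above the 50th percentile, and is normalized so that Σⱼ S₁ⱼ = r̄ · 1000
with r̄ the validation prediction–truth correlation. High-scoring genes are
the model's SVG ranking.

Supporting statistics: 1D Wasserstein distance between reference and query
expression distributions filters batch-shifted genes before training
(genes with W₁ ≥ 0.1 are dropped); mapping accuracy is scored with
rotation-invariant pairwise Pearson r and pairwise RMSE over all
inter-point distances; consistency between reference and reconstructed
expression uses bivariate Moran's I with 100/d inverse-distance weights.

## Worked example

```python
import stloc

cfg = stloc.SynthConfig(n_spots=800, n_genes=100, n_svg=25, mean_depth=2000, seed=0)
reference, truth = stloc.generate_reference(cfg)
normalized = stloc.normalize_counts(reference)

spec = stloc.ModelSpec(n_genes=100, hidden_widths=(256, 64, 16, 4))
train_cfg = stloc.TrainConfig(batch_size=128, max_epochs=100, seed=0)
cv = stloc.crossvalidate(normalized, spec, train_cfg, n_folds=5, seed=0)
print(f"fivefold pairwise r:    {cv.mean_r:.3f}")
print(f"fivefold pairwise RMSE: {cv.mean_rmse:.3f}")

normalizer = stloc.fit_coord_normalizer(reference.coords)
model = stloc.train(stloc.build_model(spec, seed=0), normalized, normalizer, train_cfg)
scores = stloc.score_genes(model)
print(f"validation mean r-bar:  {model.mean_pred_corr:.3f}")
print("top genes:", ", ".join(stloc.rank_svgs(scores, top_n=5)))
```

prints

```
fivefold pairwise r:    0.846
fivefold pairwise RMSE: 0.209
validation mean r-bar:  0.958
top genes: gene0012, gene0015, gene0001, gene0000, gene0017
```

Pairwise r of 0.85 means held-out spots are placed so that 85% of the
variation in true inter-spot distances is mirrored by the predicted ones;
the five top-ranked genes here are all truly spatially patterned by
construction (the generator's ground truth names them).

The same pipeline is available from the shell — `stloc simulate`,
`preprocess`, `train`, `predict`, `map`, `svg`, `evaluate`,
`crossvalidate` — each run writing a JSON manifest with its resolved
configuration and seed next to its outputs. See `stloc --help`.

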
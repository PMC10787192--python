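# drtransfer

Preclinical-to-clinical drug response transfer with tissue-informed
normalization, masking-based gene attribution, and knee-point biomarker
panel selection.

## The problem

Drug response labels are abundant for cancer cell lines (continuous ln IC50
from dose–response screens) but scarce for patients, whose clinical response
is at best a binary sensitive/resistant call. A regressor trained on
cell-line expression profiles transfers poorly to tumor RNA-seq because the
two cohorts differ systematically — platform, processing, and tissue
composition all shift the per-gene expression scale.

`drtransfer` implements a two-phase pipeline for this setting:

**Phase 1 — prediction.** A dense network (hidden layers of 512, 256 and 128
ReLU units, one dropout layer with p = 0.2 before the linear output) is
trained per drug on z-scored source expression against drug-wise z-scored
ln IC50, with grid-searched batch size and learning rate (5-fold CV
maximizing mean validation Pearson r, up to 1000 epochs with patience-30
early stopping) and a 10-seed mean ensemble. Target samples are normalized
**tissue-informed**: for drug D with administered tissue set T_D, each gene i
of a test sample is scaled as

    x_i = (x̃_i − μ_{i,T_D}) / σ_{i,T_D}

where the moments come from an *unlabeled* pool of target-domain samples
restricted to T_D, excluding the test samples themselves. Because any
per-gene affine cohort shift cancels under matched z-scoring, the model sees
target inputs on the scale it was trained on.

**Phase 2 — explanation.** The trained ensemble is explained by
Granger-style masking: for sample X with label y and ensemble prediction ŷ,
the error is ε_X = (y − ŷ)², and zeroing gene i gives ε_{X\{i}}. The
contribution vector Ω_X normalizes the error increases
Δε_i = ε_{X\{i}} − ε_X onto the probability simplex. These targets are
distilled into an ensemble of explainer networks (two 512-unit layers,
softmax head) by minimizing KL(Ω_X ‖ Ω̂_X); per-gene medians across
explainers, averaged over the labeled test samples and scaled to max 1, give
per-drug gene scores ω̄_i. The biomarker panel is cut at the **knee** of the
sorted score curve (kneedle: the local maximum of the gap to the line joining
the curve's endpoints).

Evaluation is rank-based: one-sided Mann–Whitney U (resistant predictions
greater than sensitive), Fisher's method for combining P values, AUROC,
precision at the k-th percentile, and the Ward merge cost between source
and target groups in the 128-dimensional latent space as a measure of
residual domain discrepancy.

## Worked example

Everything runs against the built-in synthetic generator, which plants
signal genes, tissue structure, and a configurable affine domain shift:

```python
import drtransfer as dt

ds = dt.generate(dt.SyntheticConfig(seed=1))   # 500 cell lines, 200 genes,
                                               # 10 signal genes, 60 tumors
cfg = dt.PipelineConfig(batch_sizes=(32,), learning_rates=(1e-3,),
                        ensemble_size=5, n_explainers=5,
                        explainer_subsample=150, base_seed=1)
res = dt.run_pipeline(cfg, ds.source, ds.source_response,
                      ds.target, ds.target_labels, ds.pool)
print(f"AUROC = {res.report.auroc:.3f}, P = {res.report.p_value:.2e}")
print(f"panel size = {len(res.knee.selected_gene_ids)}")
top10 = set(res.explainer_scores.ranked().head(10)['gene'])
print(f"planted genes in top 10: {len(top10 & set(ds.signal_genes))}/10")
```

prints

```
AUROC = 0.979, P = 9.78e-11
panel size = 11
planted genes in top 10: 10/10
```

i.e. the transferred model separates sensitive from resistant target samples
almost perfectly, and the explainer ranks all ten planted signal genes at
the top, with the knee cutting a panel of about the planted size.

The same pipeline is available from the shell:

```bash
drtransfer simulate --seed 1 --out sim/
drtransfer run --source sim/source.tsv --response sim/source_response.tsv \
    --target sim/target.tsv --labels sim/target_labels.tsv \
    --pool sim/pool.tsv --out run/
```

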
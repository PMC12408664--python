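# scdrp — single-cell drug-response prediction by bulk-to-single-cell transfer

Drug-response labels are plentiful for bulk cancer cell lines (GDSC, CCLE)
but scarce at single-cell resolution, where tumor heterogeneity actually
lives. `scdrp` transfers a response predictor trained on labeled bulk
expression to unlabeled single-cell RNA-seq data, producing a continuous
drug-sensitivity probability per cell, plus the downstream interpretation a
biologist needs: differentially expressed genes between predicted sensitive
and resistant populations, per-cell gene-set scores with a random-gene-set
significance test, and integrated-gradient key-gene rankings.

## Method

Let X_g be a bulk expression matrix (cell lines × genes) with binary response
labels Y_g (0 = resistant, 1 = sensitive) and X_t a single-cell matrix over
the same genes. Training proceeds in three stages:

1. **Bulk pretraining.** A denoising autoencoder (E_g, D_g) is trained to
   reconstruct X_g from a Bernoulli-masked corruption (each entry zeroed with
   probability p), minimizing MSE(X_g, D_g(E_g(X̃_g))). A predictor P —
   multi-head self-attention over the bottleneck vector (reshaped into
   tokens; per head i: softmax(Q_i K_iᵀ/√d_k)V_i with Q_i = XW_i^Q etc.)
   followed by an MLP with a sigmoid unit — is trained on E_g(X_g) under
   binary cross-entropy against Y_g.
2. **Joint adaptation.** A second DAE (E_t, D_t) is fitted to X_t, the cells
   are Louvain-clustered once in latent space, and E_g, E_t, P are then
   jointly optimized (decoders frozen) under

       L = L_class + ω·MMD²(E_g(X_g), E_t(X_t)) + θ·R_cluster

   where MMD² is the kernel maximum mean discrepancy between the two latent
   samples (multi-scale RBF, median-heuristic bandwidths) and R_cluster is
   the mean of 1 − cos(cell embedding, its cluster centroid).
3. **Transfer.** Each cell receives a sensitivity score Y_s = P(E_t(x)) ∈
   [0, 1]. Scores ≥ 0.5 are labeled sensitive for interpretation only;
   threshold-free metrics (AUC-ROC, average precision) use the raw scores.

Because real labeled single-cell drug-response datasets require external
downloads, the package ships a synthetic generator (`scdrp.simulate`) that
plants the structure the method assumes — shared latent factors, a
sensitivity axis loading marker genes, class imbalance, a per-gene affine
domain shift, Poisson count noise and dropout — so the complete pipeline is
exercisable and testable offline.

## Worked example

```python
from scdrp import SimConfig, evaluate_scores
from scdrp.pipeline import run_synthetic_pipeline

sim = SimConfig(n_genes=300, n_bulk=400, n_cells=400, effect_size=3.0,
                domain_shift=1.0, seed=1)
result, y_sc, truth = run_synthetic_pipeline(sim, seed=1)
report = evaluate_scores(result.scores.scores, y_sc.labels)
print(f"transferred single-cell AUC:  {report.auc_roc:.4f}")
print(f"average precision:            {report.average_precision:.4f}")
print(f"precision / recall / F1:      {report.precision:.4f} / {report.recall:.4f} / {report.f1:.4f}")
```

prints

```
transferred single-cell AUC:  0.9168
average precision:            0.9302
precision / recall / F1:      0.7900 / 0.8650 / 0.8258
```

The AUC is computed between the transferred per-cell sensitivity scores and
the generator's ground-truth labels: the predictor, trained only on bulk
labels, ranks ~92% of sensitive/resistant cell pairs correctly after MMD
alignment. `result.loss_trace` holds the per-step class / MMD / regularizer
/ total loss decomposition; `truth` carries the planted marker genes, which
`scdrp.interpretation.integrated_gradients` recovers as top key genes.

The same workflow is available from the shell:

```bash
scdrp simulate --config cfg.yaml --out data/
scdrp pretrain --bulk data/bulk.csv --labels data/bulk_labels.csv --config cfg.yaml --out model/
scdrp transfer --model model/ --sc data/sc.csv --config cfg.yaml --out result/
scdrp evaluate --scores result/scores.csv --truth data/sc_labels.csv --out report.json
```

Every command writes a `manifest.json` (config snapshot, seeds, input
checksums, wall-clock) from which the run can be replayed bit-identically.

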
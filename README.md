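# scdmfk

Clustering of single-cell RNA-seq UMI count matrices by joint training of a
denoising autoencoder with a **multinomial reconstruction likelihood** and an
**entropy-regularized adaptive fuzzy k-means** objective in the latent space.
The package is aimed at computational biologists who have a quantified
cells × genes UMI count matrix (10x-style MTX, dense CSV/TSV) and want soft
cluster assignments, a latent embedding, and reproducible evaluation —
including a built-in gamma-Poisson simulator for benchmarking with ground
truth, with no external downloads.

## The model

Each cell's counts X_i = (X_i1, …, X_im) are treated as n_i = Σ_j X_ij
multinomial draws over the selected genes with cell-specific probabilities
p_i on the simplex.  An encoder maps the normalized expression to a
32-dimensional embedding z_i; the decoder output feeds two heads,

    π = sigmoid(·)   (dropout-retention probabilities),
    V = exp(·)       (expected relative expression),
    p_ij = π_ij V_ij / Σ_j π_ij V_ij,

and the reconstruction loss is the multinomial negative log-likelihood
L1 ∝ −Σ_ij X_ij log p_ij.  A *direct* variant replaces the two heads with a
single softmax head producing p (useful when the zero fraction is moderate).

Clustering happens in the latent space with a robust adaptive distance

    ‖z − μ‖_σ = (1+σ) d² / (d+σ),   d = ‖z − μ‖₂,

which interpolates between Euclidean (σ→0) and squared-Euclidean (σ→∞)
behavior.  Soft memberships have the closed form

    w_ij = softmax_j( −‖z_i − μ_j‖_σ / λ ),

the minimizer of the entropy-regularized fuzzy k-means objective, and the
clustering loss is L2 = Σ_ij w_ij ‖z_i − μ_j‖_σ with w treated as fixed
coefficients.  Training minimizes L = L1 + α·L2 (α = 1 by default): first a
likelihood-only pretraining phase, then k-means center initialization, then
joint Adam steps over network weights and centers until hard assignments
stabilize.  The network is implemented directly on NumPy with hand-derived
backpropagation (validated against finite differences in the test suite).

## Worked example

Simulate a balanced 5-group dataset and cluster it:

```bash
scdmfk simulate splat-balanced --groups 5 --dropout-mid -1.5 \
    --cells-per-group 250 --seed 1 -o sim/
scdmfk run sim/ -k 5 --eval sim/labels.csv --pretrain-epochs 250 -o out/
```

The run prints the clustering quality against the simulated ground truth:

```
{"ari": 0.9662461743789402, "nmi": 0.9493431045111589}
```

ARI (adjusted Rand index) is pair-agreement corrected for chance (1 =
identical partitions, ≈0 = random); NMI is mutual information normalized by
the mean label entropy.  `out/` also contains the per-cell labels, the soft
membership matrix, the 32-dimensional embedding, the loss history, and a
manifest recording the resolved configuration, input hashes and seed so the
run can be reproduced exactly.

The same pipeline is available from Python:

```python
from scdmfk import balanced_design, run_pipeline, adjusted_rand_index

sim = balanced_design(5, dropout_mid=-1.5, seed=1, cells_per_group=250)
result = run_pipeline(sim.counts, k=5, pretrain_epochs=250, seed=1)
print(adjusted_rand_index(sim.labels.labels, result.labels))
```

Other subcommands: `scdmfk evaluate` (ARI/NMI between label files),
`scdmfk estimate-k` (gap-statistic cluster-number estimation in the latent
space), `scdmfk grid-search` (the σ ∈ {0.01, 0.1, 1, 10, 100} ×
λ ∈ {0.01, 0.1, 1} preset sweep).

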
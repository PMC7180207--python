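# Methods

## Model

The data model is a multinomial sampling view of UMI counts: sequencing
captures a small fraction of a cell's transcripts, so conditional on the
per-cell total n_i the observed counts are n_i draws over genes with
probabilities p_i.  The package estimates p_i with a denoising autoencoder.
The encoder (widths 256 → 64, ReLU) maps the z-scored expression of the
selected genes to a 32-dimensional embedding; the decoder mirrors the
encoder, and its top hidden layer feeds the output heads.

Two head parameterizations are provided:

* **standard** — two linear heads with sigmoid and exponential activations
  produce π (per-entry dropout-retention probability, in (0,1)) and V
  (expected relative expression, positive); p is their elementwise product
  renormalized per cell.  The multiplicative π acts as a learned
  down-weighting of entries likely to be false zeros.
* **direct** — a single softmax head outputs p directly.  With fewer
  parameters it can fit better when the zero fraction is moderate (the
  pipeline logs a hint when the zero fraction of the selected counts is
  below 0.7); on very sparse data the explicit dropout factor tends to help.

The reconstruction loss L1 is the multinomial negative log-likelihood per
cell, −Σ_j X_ij log(p_ij + ε), averaged over the minibatch; the multinomial
coefficient is constant in p and dropped.  Averaging (rather than summing)
over the batch keeps the clustering weight α comparable across batch sizes.
The likelihood always consumes the raw integer counts; the normalized/
z-scored view exists only for encoder conditioning.

## Clustering

Soft clustering runs in the latent space with the robust distance
‖z−μ‖_σ = (1+σ)d²/(d+σ).  σ (default 1) trades off outlier influence:
small σ gives near-linear (L2-like) growth, large σ quadratic growth.
Memberships minimize Σ_ij w_ij ‖z_i−μ_j‖_σ + λ Σ_ij w_ij log w_ij subject
to row-stochasticity, giving the softmax closed form; λ (default 1)
controls assignment softness (λ→0 is hard assignment, λ→∞ uniform).
The clustering loss backpropagates through the distances into the encoder
and the centers, but *not* through the memberships: w is recomputed in
closed form each step and treated as a constant coefficient, matching the
alternating-minimization structure of the objective.  By the envelope
theorem this semi-gradient is exactly the gradient of the soft-min
potential −λ·log Σ_k exp(−‖z−μ_k‖_σ/λ), which is how the gradient tests
verify it.

Training: Adam (learning rate 1e-4, framework-default betas), minibatch
256, likelihood-only pretraining (default 1000 epochs; desk-scale runs use
less), k-means center initialization (k-means++; 20 restarts, 300
iterations), then joint steps on L1 + αL2 until fewer than 0.1% of cells
change hard label between consecutive epochs (the stopping convention of
the deep-embedded-clustering family) or 300 epochs.  With α = 0 the
procedure reduces to the likelihood-only baseline: pretrained embedding
plus standard k-means — this is the ablation comparator.

The network is implemented directly on NumPy arrays with hand-derived
backpropagation.  Parameters are float32 (float64 available via
`ModelConfig(dtype=...)`, used by the finite-difference gradient tests).

## Preprocessing

Genes expressed nowhere are dropped, then all-zero cells.  Per-gene
normalized dispersion follows the Seurat-style recipe (variance/mean of the
median-depth-normalized expression, log-transformed, z-scored within 20
equal-width bins of log mean expression; single-gene bins score 1); the
top 500 genes by this score are kept (300–2000 supported and sweepable).
The network input is median-depth-normalized, log1p-transformed, per-gene
z-scored, clipped to ±10.  Constant genes receive an all-zero z-score
column (sd clamped to 1) rather than NaNs.  Size factors are computed over
all retained genes by default (`size_factor_scope="hvg"` restricts them to
the selected genes); the per-cell totals entering the multinomial are
always recomputed on the selected genes, since the likelihood is over that
subset.

## Simulator

The simulator emulates the Splatter gamma-Poisson generative model: gene
base means ~ Gamma(shape 0.6, rate 0.3); per group, each gene is
differentially expressed with probability 0.1, receiving a log-normal
factor (location 0.1, scale 0.2, down-regulated with probability 0.5);
per-cell library sizes ~ log-normal(11, 0.2); per-entry means are
gamma-mixed with a biological-coefficient-of-variation trend
bcv = (0.1 + 1/√mean)·√(df/χ²_df), df = 60, before Poisson sampling;
finally entries are zeroed with probability
sigmoid(shape·(log(λ+1) − mid)), shape = −1, so a larger midpoint produces
more dropout.  Midpoints −1.5 … 0.5 produce roughly 4–20% extra zeros
under the study designs; both the extra-zero and total-zero fractions are
recorded on every simulated dataset so either reading of "dropout rate"
can be checked empirically.

Two designs reproduce the simulation study: *balanced* (5–9 groups × 500
cells, 2500 genes, DE factor scale 0.2) and *imbalanced* (5 groups whose
sizes form a geometric series with ratio 0.6–1, totalling 2500 cells,
largest-remainder rounding).  Features of real data the simulator does not
emulate: batch effects, outlier genes, trajectories/continuous states,
ambient RNA, doublets.  Passing the recovery tests therefore demonstrates
correct model behavior under the stated generative assumptions, not
performance on arbitrary real tissues.

## Evaluation

ARI is the Hubert–Arabie adjusted Rand index from the contingency table;
NMI uses natural logs and, by default, the arithmetic mean of the label
entropies as normalizer (geometric/min/max available — published NMI
figures are sensitive to this choice, so it stays explicit).  Harnesses rerun the public
pipeline on downsampled cells, on matrices with non-zero entries randomly
masked to zero, and across cluster numbers K−2 … K+2.  The gap statistic
estimates K by comparing log within-cluster dispersion against uniform
reference samples from the embedding's bounding box (10 references), taking
the smallest k with gap(k) ≥ gap(k+1) − s_{k+1}.

## Numerical choices

* ε = 1e-10 inside every log and in the p-normalization denominator:
  sigmoid/exp never emit exact zeros but float underflow can.
* The exp-head preactivation is clipped to ±30 (gradient masked beyond) to
  keep float32 finite early in training.
* Soft assignments subtract the row-minimum distance before
  exponentiation, so λ = 0.01 on large distances cannot overflow.
* The σ-distance gradient uses the algebraically reduced ratio
  g'(d)/d = (1+σ)(d+2σ)/(d+σ)², finite at d = 0.
* Dispersion ties are broken by original column order; k-means and all
  random draws flow from explicit integer seeds, giving single-threaded
  bitwise reproducibility of simulator output and label files.
* Head biases are included by default (`head_bias=False` gives the pure
  linear-map form of the heads).

## Problem sizes used by the shipped checks

Full-scale runs (2500–4500 cells, 1000 pretraining epochs) are the
intended usage.  The shipped test suite and `scripts/acceptance.py` use
scaled-down protocols chosen once: recovery and ablation at full design
size (5 × 500 cells) with 200 pretraining epochs; the balanced simulation
study at 250 cells per group, one replicate per scenario, 250 pretraining
epochs (the acceptance script reports a 3×3 subgrid of the 5×5 scenario
grid; the test suite runs all 25); downsampling robustness at 5 × 300
cells with 400 pretraining epochs.  Quality depends on the number of
optimizer steps rather than epochs, so smaller datasets use proportionally
more epochs.

## Known limitations

* No batch-effect correction, doublet removal, or ambient-RNA handling;
  inputs are assumed quality-controlled.
* The multinomial likelihood conditions on per-cell totals; it does not
  model count depth itself.
* Convergence is assessed on assignment stability, not on a held-out
  likelihood; with very small λ the joint phase can stop after few epochs.
* Alternative reconstruction losses (ZINB, masked/weighted MSE) and
  variational latent priors are out of scope.
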
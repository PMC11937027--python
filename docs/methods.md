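# Methods

## Model

One EEG clip is one attributed graph `G = {A, X}` over `N` channels.
The detector is a variational graph autoencoder with one twist: the same
encoder weights process two views of every clip,

* the **structural view** `{A, X}`, in which a channel's representation
  aggregates its graph neighborhood through the symmetrically
  normalized adjacency (`GCN(X, A|W) = φ(D^{-1/2} A D^{-1/2} X W)`), and
* the **semantic view** `{I, X}`, identity aggregation, in which a
  channel sees only its own features.

One shared hidden GCN layer (ReLU) feeds two linear GCN heads producing
per-node means and log-variances; each view therefore yields a per-node
diagonal Gaussian posterior.  Embeddings are drawn with the
reparameterization trick during training and replaced by the posterior
means at test time, so scores are deterministic.

The per-clip objective is `L = L_inv + λ·L_dco + β·L_kl + L_dec`:

| term | form | role |
|---|---|---|
| `L_inv` | `‖Z'_st − Z'_se‖²_F` | views agree on normal channels |
| `L_dco` | `‖Z'ᵀZ' − I‖²_F`, both views | prevents collapsed embeddings |
| `L_kl`  | closed-form KL of both posteriors from N(0, I) | aligns the two distributions via a common prior |
| `L_dec` | `‖X − X̂‖_F + ‖A − Â‖_F` | embeddings must retain clip content |

`Z'` is the column-standardized embedding divided by `√N`, so `Z'ᵀZ'` is
the column correlation matrix and the decorrelation target `I` is
scale-consistent.  The decoder fuses the views (`Z_f = Z_st + Z_se`),
reconstructs attributes with a 2-layer MLP (ReLU hidden, linear output)
and structure with a logistic-squashed Gram matrix `σ(Z_f Z_fᵀ)`, so the
structure target (adjacency weights in [0, 1]) and its reconstruction
live on the same scale.

**Anomaly score.** `s_i = ‖z'_st,i − z'_se,i‖²`, the per-node term of
`L_inv` (the node scores of a clip sum exactly to its invariance loss).
A channel whose own features no longer match its structural context —
equivalently, whose structural/semantic correlation is weak — scores
high.  Clip scores are the mean (optionally max) of channel scores.

### Assumptions

* All clips share one montage; channel order is fixed (the packaged
  19-electrode 10-20 table, unit-sphere coordinates).
* Normality of the training set: the model is a one-class method; any
  contamination weakens the learned agreement between views (the CLI
  refuses training inputs whose manifest flags anomalies).
* Within-clip scoring is relative: embeddings are normalized per clip,
  so scores compare channels against the other channels of the same
  clip.

## Key parameters

| parameter | default | units / notes |
|---|---|---|
| clip window | 12 s @ 250 Hz | one clip = one graph |
| features `D` | 64 | log-magnitude of the first 64 DFT bins, row z-scored (≈ 0–5.3 Hz resolution steps); `raw` downsampling mode available |
| distance kernel `τ` | 1.0 | on unit-sphere electrode coordinates |
| distance cutoff `k` | 0.9 | same units; pairs farther apart get weight 0 |
| neighbors kept (corr/DTF) | 3 | strongest |normalized correlation| per node, ties to the lower index |
| dims `h`, `d` | 64, 32 | hidden and latent widths |
| `λ` (decorrelation) | 0.1 | trade-off inside the CCA term |
| `β` = `w_kl` | 0.01 | see "KL weighting" below |
| optimizer | Adam, lr 1e-3, 200 epochs | one full-batch step per clip per epoch |
| ε | 1e-8 | all variance/denominator floors |

### KL weighting

With the KL term at full weight the objective is minimized by posterior
collapse: both posteriors sit exactly on the prior (`L_kl → 0`), the
embeddings carry no clip information, and the detector is blind (node
AUC ≈ 0.5 on the synthetic benchmark).  This is the standard VAE
failure mode, and the standard remedy applies: the KL is β-weighted with
`β = 0.01`, which keeps the alignment regularization active (posterior
scales stay comparable across views) while the CCA and reconstruction
terms shape the embeddings.  `β` is exposed in `LossConfig`.

## Synthetic data: what it does and does not emulate

`GeneratorSpec` produces 19-channel clips as a mixing-weighted sum of 4
band-limited (1–30 Hz, 4th-order Butterworth-filtered noise) unit-
variance latent sources plus white sensor noise (σ = 0.1 of source
scale).  Source loadings fall off as a Gaussian of electrode–source
distance on the scalp sphere, so nearby channels share sources and are
strongly correlated — which is exactly the structure the correlation and
influence graphs need to be non-trivial.

The benchmark follows the anomalous-channel protocol: features of every
35 consecutive normal clips are averaged without overlap (remainder
dropped); each averaged clip is independently corrupted with probability
`p_inject` (default 0.03), choosing one node uniformly and applying both
corruptions — adjacency row/column set to 1 against all other nodes, and
feature row replaced by that of the Euclidean-farthest node.  At most
one node per averaged clip is corrupted, and the clip label is the OR of
its node labels.

Not emulated: physiologically realistic seizure morphology (spike-wave
complexes, evolution in time), artifacts (EMG, eye blinks, electrode
pops), inter-patient variability, and non-stationarity.  Passing the
synthetic benchmark therefore shows that the pipeline recovers
*structural/contextual decoupling* of a channel from its neighborhood —
the mechanism the method targets — not that it detects clinical seizures
on real recordings.

## Numerical choices

* **Correlation dialect.** The pairwise weight divides a mean-centered
  lag-zero cross-correlation by the product of centered row norms —
  i.e. the Pearson correlation of the two feature rows.  Ranking for the
  top-3 neighborhood uses the absolute value; the signed value is
  stored.  The influence ("DTF") graph uses the *uncentered-normalized*
  numerator convention as printed in its defining ratio, with the same
  top-3 neighborhood and an ε-floored denominator.
* **Normalization.** GCN normalization adds self-loops to every
  non-identity graph (sparse correlation graphs could otherwise have
  zero-degree rows); a matrix equal to `I` passes through unchanged.
  The check is on the matrix, not the builder tag, so corruption that
  adds edges to an identity-built graph is normalized — and aggregated —
  like any other graph.
* **Unsquared Frobenius norms** in `L_dec` are smoothed as
  `sqrt(‖Δ‖² + ε²)` so the gradient exists at a perfect reconstruction.
* **Sign of the KL term.** The alignment term is minimized as +KL (the
  ELBO convention); minimizing its negation would push the posteriors
  away from the shared prior, the opposite of the alignment goal.
* **`√N` scaling** of normalized embeddings is a division, the only
  reading under which `Z'ᵀZ'` is a correlation matrix and comparing it
  to `I` is meaningful.
* **Ties and determinism.** Top-3 ties break toward the lower channel
  index; all stochastic steps (init, sampling, generation, injection)
  draw from `numpy` generators seeded from a single user seed, so every
  pipeline output is bit-reproducible; checkpoints round-trip through
  JSON exactly.
* **Degenerate inputs.** Zero-variance channels are ε-floored with a
  warning; graphs with `N ≤ 3` keep all off-diagonal correlation edges;
  the influence graph requires `N ≥ 3`; training aborts with the name of
  the first non-finite loss term.
* **Autodiff.** The training loop differentiates the objective with a
  small reverse-mode tape over NumPy arrays (`eegcorr._autodiff`);
  gradient correctness is pinned by central finite differences at 1e-4
  relative tolerance in the test suite.

## Open design points, resolved

* The feature matrix content is a free choice; log-spectral magnitudes
  are the field's common default for EEG graphs and make the sinusoid
  unit test exact.  Raw downsampling is retained as an option.
* The variational heads read the shared hidden layer's output (not the
  raw features): one shared layer then two heads is the smallest
  architecture with a genuinely shared representation.
* Sampling happens at train time only; scores use posterior means.
  Sampled scoring is available via `embed(..., sample_seed=...)`.
* Clip-level aggregation is the mean of channel scores (max available):
  with at most one corrupted channel in 19, the mean dilutes less than
  one might fear and is robust to a single noisy channel score.
* The specificity operating point is the 95th percentile of
  normal-channel scores, reported together with the threshold.
* Two injection rates are quoted for the benchmark protocol (3% and
  0.03%); the default is 3% per averaged clip — the lower figure would
  produce essentially no positives at test scale — and the rate is a
  parameter everywhere.

## Problem sizes

The shipped study conditions: training on 50 averaged clips (1750
generated normal clips, window 35), 200 epochs; evaluation on 20–50
replicates of 10 averaged clips with `p_inject` raised to 0.5 so the
small test sets contain positives.  At these sizes a full
train-plus-evaluate cycle takes well under two minutes on one CPU core;
all sizes are arguments of `make_benchmark`/`fit` and scale linearly.

## Known limitations

* No temporal modeling within or across clips; each clip is scored
  independently.
* The per-clip embedding normalization makes scores relative to the
  clip; a clip in which *every* channel is anomalous would normalize the
  anomaly away.
* One montage (19-channel 10-20) is packaged; other montages require
  user-supplied coordinates.
* The NumPy training loop is single-threaded and sized for
  19-channel graphs; it is not a general-purpose GNN engine.
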
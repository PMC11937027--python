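# eegcorr

Unsupervised detection of anomalous (seizure-affected) EEG channels by
**graph correlation analysis**.

Scalp EEG channels normally move together: a channel's signal is well
predicted by its neighbors, whether neighborhood is defined by electrode
distance or by functional connectivity.  During a seizure, affected
channels decouple from that structure.  `eegcorr` turns this intuition
into an unsupervised detector that needs **no seizure data at training
time**: it learns, from normal clips only, how each channel's own
features relate to what its graph neighborhood predicts, and flags
channels where that relationship breaks.

## Method

Each fixed-length clip becomes an attributed graph `G = {A, X}` with one
node per channel: `X ∈ R^{N×D}` holds per-channel log-spectral features
and `A` is one of six adjacency builders (electrode distance with a
Gaussian kernel, top-3 normalized cross-correlation, uniform 0.5,
complete, correlation-influence "DTF", or the identity matrix).  A
**weight-sharing variational GCN** encodes two views with the *same*
parameters:

* structural view `q(Z_st | X, A)` — each node aggregates its neighbors
  through the symmetrically normalized adjacency
  `GCN(X, A | W) = φ(D^{-1/2} A D^{-1/2} X W)`;
* semantic view `q(Z_se | X, I)` — identity aggregation, each node sees
  only its own features.

Both views yield per-node diagonal Gaussian posteriors, aligned to a
standard-normal prior by a KL term.  Sampled embeddings are trained with
a soft-CCA objective — an invariance term `L_inv = ‖Z'_st − Z'_se‖²_F`
that makes the views agree on normal data, plus a decorrelation term
`L_dco = ‖Z'ᵀZ' − I‖²_F` per view that prevents collapse — and a
reconstruction term `L_dec = ‖X − X̂‖ + ‖A − Â‖` through a fusion
decoder (`Z_f = Z_st + Z_se`, MLP for attributes, logistic Gram matrix
for structure).  The total objective is

```
L = L_CCA + β·L_kl + L_dec,    L_CCA = L_inv + λ·L_dco
```

At test time the **anomaly score of channel i** is its contribution to
the invariance loss, `s_i = ‖z'_st,i − z'_se,i‖²`: weak correlation
between a channel's own features and its structural context means a
large score.  Clip scores aggregate channel scores.

Because clinical seizure corpora are access-controlled, the package
ships a synthetic benchmark: correlated 19-channel clips (10-20 montage,
band-limited latent sources mixed with spatial falloff), averaging of
every 35 normal clips, and injection of at most one corrupted node per
averaged clip — connected to all other nodes (structural) and given the
feature vector of the Euclidean-farthest node (contextual).

## Worked example

```python
import eegcorr as ec

spec = ec.GeneratorSpec()                       # 19 ch, 250 Hz, 12 s clips
train = ec.make_benchmark(spec, n_clips=1750, window=35, p_inject=0.0, seed=11)
model = ec.GraphCorrelationModel(train.graphs)  # 50 averaged normal clips
res = model.fit(epochs=200, seed=11)
print(res.summary())

test = ec.make_benchmark(spec, n_clips=350, window=35, p_inject=0.5, seed=31)
report = res.evaluate_nodes(test.graphs, test.node_labels)
print(f"node AUC={report.auc:.3f} AP={report.ap:.3f} SPC={report.specificity:.3f}")
```

prints (abridged):

```
Graph Correlation Anomaly Detector
======================================================
clips (training):      50
channels / features:   19 / 64
graph kind:            corr
...
term             epoch 0         final
L_inv            63.7340       32.0515
L_dco           110.0326      228.6501
L_kl             44.7095      628.6743
L_dec            35.6213       13.5212
L_total         110.8056       74.7244
======================================================
node AUC=0.992 AP=0.810 SPC=0.946
```

`L_inv` halves during training — the two views learn to agree on normal
channels — and the trained detector ranks injected channels almost
perfectly (AUC ≈ 1) while keeping ~95% specificity at a threshold set to
the 95th percentile of normal-channel scores.

The same pipeline is available from the shell:

```bash
eegcorr benchmark -o trainset --p-inject 0    # normal-only training set
eegcorr benchmark -o testset --seed 99        # corrupted test set
eegcorr train -i trainset -o fit
eegcorr score --checkpoint fit -i testset -o scored --heatmap
```

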
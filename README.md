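# eegmind

EEG brain-state classification with temporal graph attention, hierarchical
spatial graphs over channels and regions, and connectivity-validation
statistics — exercisable end to end on synthetic EEG with known ground
truth.

## Who this is for

Researchers who want a transparent, fully testable reference implementation
of a graph-attention EEG window classifier: the preprocessing chain
(band-pass, ICA artifact removal, bad-channel handling, normalization), the
model itself, the training and cross-validation protocol, and the
statistics used to compare a learned channel graph with measured functional
connectivity. Every component runs on a synthetic generator whose spectral
signatures and inter-channel correlations are known exactly, so each claim
the package makes is checked against ground truth rather than downloads.

## The model

A recording X ∈ ℝ^{C×T} (C channels, microvolts) is segmented into windows
X̃ ∈ ℝ^{C×W} that are classified independently into K classes:

- **Temporal stream (DT-GAM).** A window is grouped into non-overlapping
  temporal patches that become nodes of a temporal graph. Scaled
  dot-product attention A_t = softmax(Q_t K_tᵀ / √d_t) over the graph's
  edge mask (full or banded) gives a row-stochastic, input-dependent
  adjacency; temporal graph convolution H^(l+1) = σ(A_t H^(l) W^(l)) refines
  the node embeddings, and mean pooling yields the temporal feature h_t.
- **Spatial stream (HGRA).** Channels form the first level of a graph
  hierarchy; user-supplied partitions group them into regions. Each level
  runs graph convolutions with the symmetric-normalized adjacency
  D^{-1/2}(A+I)D^{-1/2}, embeddings are pooled upward, and a principal
  aggregation/distribution (PAD) step shares a global embedding back to
  every level. The level-1 adjacency can be learned from channel features
  with a symmetric nonnegative scorer W_ij = f(x_i, x_j, θ) and optionally
  regularized toward measured functional connectivity with an alignment
  loss ‖C − W‖²_F. The top level's readout is the spatial feature h_s.
- **Fusion head (STFM).** h_f = ReLU(W_f [h_t ; h_s] + b_f) and
  ŷ = softmax(W_o h_f + b_o), trained with mean cross-entropy (plus the
  optional weighted alignment term).

Connectivity validation: Pearson functional connectivity C_ij, the graph
similarity index S = ΣC_ij·W_ij / (√ΣC_ij² · √ΣW_ij²), Newman modularity
Q = (1/2m) Σ_ij [W_ij − k_i k_j/2m] δ(g_i, g_j), a Welch two-sample t on
edge strengths between conditions, and normalized-degree node importance.

## Worked example

```python
from eegmind import two_class_spec, generate_dataset, EEGMindModel, TrainConfig, train, evaluate
from eegmind.experiments import benchmark_model_config
from eegmind.preprocessing import normalize_windows
from eegmind.training import stratified_split

ds, truth = generate_dataset(two_class_spec(n_per_class=200, seed=1))
ds = normalize_windows(ds)
train_set, val_set, test_set = stratified_split(ds, seed=1)
model = EEGMindModel(benchmark_model_config(seed=1))
model, history = train(model, train_set, val_set,
                       TrainConfig(lr=1e-2, max_epochs=30, seed=1))
report = evaluate(model, test_set)
print(f"best val acc {history.val_accuracy.max():.3f}  "
      f"test acc {report.accuracy:.3f}  test AUC {report.auc:.3f}")
```

prints

```
best val acc 0.975  test acc 0.975  test AUC 0.995
```

meaning the full model separates the alpha-dominant from the beta-dominant
synthetic class almost perfectly on held-out windows within 30 epochs: the
generator's two classes differ in band power (8–12 Hz vs 13–30 Hz dominant)
and in inter-channel connectivity, and the learned classifier recovers that
separation from raw normalized windows.

The same pipeline is scriptable from the shell:

```sh
eegmind synth  --spec cfg.yaml --out data/
eegmind train  --config cfg.yaml --data data/ --out run/
eegmind robustness --config cfg.yaml --run run/ --data data/
eegmind metrics    --config cfg.yaml --run run/ --data data/
```

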
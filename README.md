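# brainedge

Discovering the discriminative connections of a functional brain network
from multichannel EEG.

Given EEG trials with binary outcomes (e.g. correct vs incorrect responses
in a cognitive task), `brainedge` turns each trial into a weighted
connectivity network over the sensors, classifies the trials from the edge
weights with a family of robust support-vector machines, and ranks the
edges to find the small subset of connections that actually carries the
class difference. Because real task EEG of this kind is rarely shareable,
the package ships a synthetic coupled-oscillator generator with a planted
ground-truth edge set, so the whole pipeline is testable end to end.

## What it computes

**Connectivity.** For channels *x*, *y* the package builds either the
Pearson correlation matrix or the band-resolved phase-locking value (PLV).
Phases come from convolution with a complex Morlet atom
Ψ(t) = exp(−t²/2σ_t²)·exp(2iπft) with σ_t = 7/f; the PLV of a pair is

    PLV = mean_t | (1/E) Σ_e exp(i·ΔΦ(t, e)) |

the per-time-bin modulus of the mean unit phasor of the phase difference
ΔΦ across an ensemble of E nonoverlapping 1-s epochs, averaged over bins
and then over the band's center frequencies. An N-channel matrix is
symmetric with zero diagonal and flattens to N(N−1)/2 features
(61 channels → 1830 edges). Optional baseline normalization z-scores the
PLV time course against the pre-stimulus epochs, per frequency.

**Classifiers.** Three families with a common fit/predict surface:

* soft-margin SVM — min ½‖w‖² + C Σξᵢ, linear or Gaussian kernel;
* twin-bounded SVM — two nonparallel hyperplanes, each solved through its
  regularized dual; prediction by normalized proximity
  argmin_k |w_kᵀx + b_k|/‖w_k‖;
* ξ-SOCP SVM — a robust machine whose per-class chance constraints
  (error rate ≤ η_k under the worst distribution with the class moments)
  become second-order cone constraints
  wᵀμ₁ + b ≥ 1 − ξ + κ₁√(wᵀΣ₁w),  κ_k = √(η_k/(1−η_k)),
  with one shared slack ξ — in both a linear and a kernelized form.

**Edge selection.** Fisher score F_j = |μ_j⁺ − μ_j⁻|/(σ_j⁺² + σ_j⁻²);
recursive feature elimination with the margin criterion
W²(α) = Σ αᵢα_s yᵢy_s K(xᵢ, x_s) (which reduces to w_j² for linear
kernels, and extends to the linear ξ-SOCP model); and the consensus rule
that intersects the top-k edges of two rankings.

**Evaluation.** Nested stratified 10-fold cross-validation: edges are
ranked and hyperparameters (C, cᵢ, σ over powers of two 2⁻⁷…2⁷;
η ∈ {0.2, 0.4, 0.6, 0.8}; edge counts {10, 20, 50, 100, 250, 500, 1000,
1830}) are tuned strictly inside each outer training fold; the untouched
outer test folds give the reported accuracy.

## Worked example

```python
import numpy as np
from brainedge import (SyntheticConfig, generate_dataset, build_dataset,
                       FrequencyBand, fisher_scores, rfe_rank, consensus_edges)

config = SyntheticConfig(n_channels=12, n_trials_pos=30, n_trials_neg=30,
                         planted_edges=((0, 3), (4, 9), (7, 11)),
                         coupling_pos=0.3, coupling_neg=1.2, seed=7)
data = generate_dataset(config)
features = build_dataset(data.recordings, data.labels,
                         measure="plv", band=FrequencyBand.beta())
print(f"features: {features.X.shape[0]} trials x {features.X.shape[1]} edges")

fisher = fisher_scores(features.X, features.y)
print("top-3 Fisher edges:", [features.edge_index[c] for c in fisher.top(3)])

rfe = rfe_rank(features.X, features.y, schedule=(66, 30, 10, 3))
consensus = consensus_edges(fisher, rfe, k=10, edge_index=features.edge_index)
print("consensus edges (top-10 Fisher ∩ top-10 RFE):", consensus.edges)
```

prints

```
features: 60 trials x 66 edges
top-3 Fisher edges: [(4, 9), (7, 11), (0, 3)]
consensus edges (top-10 Fisher ∩ top-10 RFE): [(4, 9), (0, 3), (7, 11), (2, 8), (5, 6), (8, 9), (4, 6)]
```

The three planted edges — the pairs whose oscillations were generated with
class-dependent phase coupling — head the Fisher ranking and survive the
consensus intersection; the extra consensus entries are chance agreements
between the two rankings on null edges, which is why the consensus set is
read jointly with the accuracy-versus-edge-count curve when choosing k.

The same pipeline is scriptable from the shell:

```sh
brainedge simulate --channels 61 --trials-pos 100 --trials-neg 180 -o ds/
brainedge features -i ds/ --measure plv --band beta -o features.csv
brainedge evaluate -i features.csv --family svm --kernel linear \
    --ranking fisher -o report.json
brainedge select -i features.csv --top-k 50 -o selection/
```

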
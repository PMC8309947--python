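# snncluster

Explainable dynamic clustering of streaming multichannel time series (EEG and
similar spatiotemporal brain data) in a brain-inspired spiking neural network,
with spike-pattern feature selection, cluster-validity scoring, human-readable
spatiotemporal rules, and a rank-order deSNN classifier.

## Who this is for

Researchers who model multichannel neurophysiological recordings with
reservoir-style spiking neural networks and want to see *why* the model
separates two groups of subjects — which channels matter, which brain regions
interact, and in what temporal order spike activity unfolds — rather than only
a classification accuracy.

## The method

A recording sample is a channel-by-time matrix. The pipeline:

1. **Spike encoding.** Temporal-contrast thresholding of first differences:
   channel *c* emits an excitatory spike (+1) at time *t* if
   `x_c(t) − x_c(t−1) > θ_c`, an inhibitory spike (−1) if the fall exceeds
   `θ_c`, else nothing. `θ_c` defaults to half the SD of the channel's first
   differences, pooled over the data set.
2. **Reservoir.** Neurons on a 3-D grid spanning the electrode montage; each
   channel injects into its nearest grid neuron. Leaky integrate-and-fire
   dynamics, `τ_m dv/dt = v_rest − v + R·I(t)`, Euler-stepped at the raster
   rate, with spike-timing-dependent plasticity on the local small-world
   connections: `F(Δt) = A₊ e^{Δt/τ₊}` for `Δt < 0`, `−A₋ e^{−Δt/τ₋}` for
   `Δt ≥ 0`, where `Δt = t_pre − t_post`.
3. **Dynamic clustering.** The transmitted-spike counts `A[i,j]` are
   symmetrised (`A′ = A + Aᵀ`, zero diagonal), normalised
   (`S = D A′ D`, `D_ii = 1/√T_i`), and cluster memberships spread from the
   input neurons to the steady state `F* = (I − αS)⁻¹ F_src` with
   `α ∈ (0,1)`. Each neuron takes the label `argmax_j F*_{ij}`; snapshots
   over training give evolving clusters, and neurons exchanged between
   adjacent clusters across snapshots form *fuzzy boundaries*.
4. **Feature selection.** Per cluster and sample, the mean member potential
   `μPSP(t)` is condensed to its peak `P_max`, area under the curve
   `∫ P(t) dt` and midrange `(max+min)/2`; a two-sample Welch *t*-test per
   channel ranks channels by class separation.
5. **Validity.** A connection-weight silhouette per neuron,
   `s(i) = (x(i) − y(i)) / max(x(i), y(i)) ∈ [−1, 1]`, with cohesion and
   separation means weighted by the membership values `F*`.
6. **Rules.** Thresholding `μPSP(t) ≥ ℓ` gives per-cluster spike-event
   sequences; every run of `ℒ` consecutive events is an *action*, and actions
   grouped by time order render as
   `IF {CP4, ord1} AND {Fp2 F3, ord2} ... THEN Output = class`.
7. **Classification.** One output neuron per training sample, rank-order
   initialised (`W = mod^order`, earliest spike largest) and drift-adapted,
   with nearest-neighbour prediction and leave-one-out cross-validation.

Since clinical EEG is rarely shareable, the package ships a synthetic
generator that emulates the study conditions: two classes, 26 channels of the
10–20 montage, 75 time points, ~20 samples per class, with a configurable
subset of channels carrying a class amplitude effect measured in noise SDs.

## Worked example

```python
import numpy as np
import snncluster as sc

# two-class synthetic EEG: 20 epochs/class, 26 channels x 75 time points,
# amplitude effect of 2 noise-SD planted on eight 10-20 channels
data = sc.generate_dataset(effect=2.0, seed=1)
order = np.random.default_rng(1).permutation(data.n_samples)
rasters = [sc.encode_samples(data)[i] for i in order]
labels = data.labels[order]

model = sc.init_reservoir((7, 7, 6), seed=1)          # 294-neuron desk-scale grid
log = sc.train_unsupervised(model, rasters, snapshot_every=75, record=True)

traces = sc.compute_traces(model, log, rasters)
summaries = sc.psp_summaries(traces, log.sample_bounds, labels)
ranking, top = sc.select_features(summaries, "area", k_top=8)
print("top-8 channels:", [data.channel_names[c] for c in top])

final = log.frames[-1]
report = sc.silhouette(model, final.labels, final.F_star)
print(f"mean silhouette over clusters: {report.per_cluster_mean.mean():.3f}")

result = sc.loocv(data, grid=(7, 7, 6), seed=1, shared_reservoir=True)
print(f"LOOCV accuracy: {result.accuracy:.2f} over {result.n_folds} folds")
```

Output:

```
top-8 channels: ['C3', 'CPz', 'F4', 'Pz', 'C4', 'Fz', 'T6', 'P4']
mean silhouette over clusters: 0.323
LOOCV accuracy: 0.90 over 40 folds
```

The eight recovered channels are exactly the eight planted ones (the
generator's default planted set), the positive silhouette says neurons sit in
coherent clusters, and restricting attention to informative channels is what
drives the classification accuracy.

## Command line

```bash
snncluster generate --out data/ --effect 2 --seed 1     # write a dataset
snncluster run --synthetic --seed 1 --out run1/          # full pipeline
snncluster run --config cfg.yaml --stage cluster         # resume one stage
```

`run` writes a frame log (HDF5), feature ranking and PSP summaries (CSV),
silhouette report (CSV), fuzzy-boundary report (CSV), rules (text + JSON), a
cross-validation report (JSON) and a manifest carrying the config hash and
seed. All stages are deterministic given the config and seed.

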
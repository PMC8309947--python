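# Methods

This note records the modelling choices behind `snncluster`: what each stage
assumes, which parameters matter and why their defaults are what they are,
what the synthetic data generator does and does not emulate, and the numerical
decisions a maintainer would otherwise have to reverse-engineer.

## Data model and synthetic generator

A sample is a real channel-by-time matrix; a data set is a list of samples
with one integer class label each and a shared channel ordering. The bundled
montage places the 26 extended 10–20 electrodes (Fp1 … Oz; T3/T4/T5/T6 are the
classic names for T7/T8/P7/P8) on a unit-sphere head using standard spherical
angles. The coordinates are approximate: only relative geometry (which
electrodes are neighbours, roughly how far apart) matters to the method, not
absolute anatomical position.

`generate_dataset` emulates a two-group ERP-window study: per channel a
sinusoid with fixed per-channel frequency (2–8 cycles per 75-point window),
uniformly random phase per sample, plus Gaussian noise of SD 0.5 (base
amplitude 1). Class 2 scales the *whole trace* of the planted channels by a
gain chosen so the oscillatory amplitude rises by `effect` noise SDs. The gain
applies to signal and background together, as band-power differences do in
real EEG; an early variant that scaled only the sinusoid left the class
difference invisible to first-difference encoding, because the unscaled noise
dominates the temporal contrasts. The default planted set is the eight
channels most often reported as discriminative in inhibition-task studies
(Fz, F4, C3, C4, CPz, T6, Pz, P4). At `effect = 0` the two classes are
exchangeable by construction.

What the generator does **not** emulate: 1/f background spectra, channel
cross-correlation from volume conduction, artifacts, non-stationarity within a
window, and latency (rather than amplitude) effects. Passing tests therefore
show the pipeline recovers *amplitude-coded* channel effects under clean
conditions; they do not certify performance on real EEG.

## Encoding

Spikes are strict threshold crossings of first differences (`|Δ| > θ` fires;
equality does not, so a flat signal at `θ = 0` stays silent). The "auto"
threshold is 0.5 × SD of the first differences; `encode_samples` pools the SD
over the whole data set so that both classes face the same threshold —
per-sample thresholds would normalise away exactly the amplitude differences
of interest. Time is abstract (one step per column); no sampling rate is
assumed.

## Reservoir

* **Geometry.** Default grid 10×12×10 (1200 neurons) spanning the montage
  bounding box plus 10% padding; a 7×7×6 grid (294 neurons) is the smallest
  bundled shape that still maps all 26 electrodes to distinct input neurons
  and is used throughout the test suite.
* **Connectivity.** All ordered pairs within radius `r` are connected; weight
  magnitude ~ U(0,1) × (nearest grid spacing / distance), 80% excitatory /
  20% inhibitory. The default `r` is 1.1 × the largest grid spacing — a
  deliberately *local* neighbourhood. Wider radii mix the drive of several
  channels into every cluster and visibly destroy the channel specificity of
  the cluster PSP traces (planted-channel recovery drops from ~100% to
  ~50–80% in pilots at 1.5×).
* **LIF.** `τ_m = 10` steps, `v_rest = 0`, `R = 1`, `θ = 0.5`, `dt = 1`,
  refractory 2 steps. The membrane is floored at `v_min = −0.5` (an
  inhibitory-reversal bound, standard in discrete LIF implementations);
  without it inhibitory spikes park the membrane far below rest, suppressing
  subsequent firing and polluting the PSP statistics with large negative
  excursions. Recorded "PSP" traces use the pre-reset potential, so
  suprathreshold overshoot is visible to the analytics.
* **Input.** Each raster event injects ±10 current units into its channel's
  input neuron — enough to fire it from rest within one step, so input-neuron
  firing tracks the channel's (positive) event stream.
* **STDP.** `A₊ = 0.01`, `A₋ = 0.012` (slight depression bias for stability),
  `τ₊ = τ₋ = 10`, weights clipped to [−1, 1]. Pairing is nearest-spike within
  a window of 3·max(τ₊, τ₋); simultaneous spikes pair with each other's
  *previous* spikes (pre-update timestamps), a standard nearest-neighbour
  approximation. The spike log counts a transmission `i→j` whenever `i` fires
  over a live connection, using the fixed initial topology mask.
* **Stream order.** Samples are streamed in a seeded random permutation.
  STDP drifts the weights over the stream, so streaming class blocks would
  confound drift with class: it both miscalibrates the `effect = 0` null and
  masks planted channels. Under a random order the labels remain exchangeable
  with respect to stream position (the null p-value fraction at 5% measured
  0.052 over 20 replicates).

## Clustering

The affinity is the symmetrised spike log. Normalisation uses
`D_ii = 1/√T_i` (symmetric normalised affinity): its spectral radius is ≤ 1,
so `αS` is a contraction for any `α < 1` and the linear system
`(I − αS) F* = F_src` is always solvable; the literal `D_ii = 1/T_i` reading
is available via `normalization="inverse"`. `α` defaults to 0.9.

Two numerical details:

* The update `F(t+1) = αSF(t) + (1−α)F_src` converges to
  `(1−α)(I−αS)⁻¹F_src`; the iterative mode rescales by `1/(1−α)` so both
  modes return the same matrix, which reduces to `F* = F_src` exactly when no
  spikes have been exchanged. The rescaling cannot change any argmax label.
  The iteration stops when the per-step change guarantees (via the
  contraction bound) that the rescaled result is within `tol` of the closed
  form.
* Snapshots during training use the sparse path (the spike graph only has
  entries on local connections) with warm starts from the previous frame.

Ties in the per-row argmax break to the lowest column index. Neurons with an
all-zero membership row (unreached by any spike path) fall back to the
cluster of the geometrically nearest input neuron and are flagged; the
partition invariant (cluster sizes sum to N) holds at every frame. Cluster
adjacency — used for fuzzy-boundary reporting and silhouette separation — is
"input neurons within 2× the median nearest-neighbour inter-electrode
distance", overridable by an explicit pair list.

Fuzzy boundaries are computed from label churn: a neuron belongs to boundary
(a, b) iff its label was a at some frame and b at another. With a single
frame the result is empty (with a warning), since churn is undefined.

## Trace analytics and feature selection

`μPSP(t)` is the arithmetic mean of the member potentials under the
frame-current membership (frame values held constant between snapshots, so
all five cluster series share the streamed time axis). The per-sample area
uses a unit-step rectangle sum (a single point has area equal to its value);
the trapezoidal rule is available. Welch's t-test (unequal variances)
compares the two classes per channel; raw p-values are ranked without
multiple-testing correction because the output is a ranking, not an
inference; a "mutual" mode intersects the top-k sets of all three statistics.

The default statistic is `area`: it integrates the class drive difference
over the whole sample, while `P_max` is an extreme-value statistic with
visibly lower power on the same runs. All three remain available.

## Silhouette validity

Cohesion `x(i)` is the mean |weight| of `i`'s outgoing connections to
same-cluster neurons times `F*[i, own centre]`; separation `y(i)` averages,
over the clusters adjacent to `i`'s own, the mean |weight| into that cluster
times the membership to its centre (clusters receiving no connections
contribute 0). Absolute weights are the default: sign-mixed means can invert
the cohesion semantics (`use_abs_weights=False` restores raw weights, with
the final score clipped to [−1, 1]). `s(i) = 0` when both terms vanish, and
neurons with no connections at all are flagged with `s = 0`.

## Rule extraction

The per-cluster event threshold `ℓ` defaults to mean + 1 SD of that cluster's
`μPSP` trace; the event comparison is `≥` (equality fires). The action window
`ℒ` defaults to 3 steps. The window scan records *every* all-ones window of
length `ℒ` (overlapping windows included), from baseline 1 to `T − ℒ + 1`;
the streaming formulation's literal loop bound (`baseline < T − ℒ`), which
can skip the trailing windows, is available as `inclusive_tail=False`.
Actions whose baselines agree after integer division by `ℒ` share a temporal
order group; orders run 1..n over groups. In the pipeline, rules are
extracted per class from the class-mean `μPSP` traces on the single shared
reservoir (averaging the per-sample segments of that class); training one
reservoir per class is the obvious alternative and would double the training
cost for the same rule syntax. Rules are explanatory artifacts only — they
play no part in classification.

The text rendering follows the `IF {channels, ord} AND … THEN Output = c`
syntax and round-trips the (channels, order) structure; baselines survive
only in the JSON export, because the field syntax does not carry them.

## deSNN classification

Rank-order initialisation `W_i = mod^rank(i)` over first-spike times (ties to
the lower neuron index), then ±drift per extra-spike/silent-step with a
single floor at zero at the end of the sample (the stepwise alternative makes
the final weight depend mostly on the trailing burst). `mod` defaults to
0.995: with oscillatory inputs of random phase, the *order* of first spikes
is arbitrary, and a small `mod` (e.g. 0.9) makes the weight vector pure
timing noise — at 0.995 the vector encodes population participation (who
spiked, how much), which is where the class information lives. `drift`
defaults to 0.005. Prediction is nearest-neighbour (Euclidean) over output
neuron weight vectors.

LOOCV retrains the unsupervised phase per fold on the training samples only
(leak-free default). `shared_reservoir=True` trains the reservoir once on all
samples — the typical protocol for streaming SNNs, defensible because the
unsupervised phase never sees labels — and is much faster since each sample's
replay is reused across folds. Note that LOOCV with nearest-neighbour is
slightly pessimistic under the null (removing the test sample leaves its own
class one sample short), noticeable at very small n.

## Problem sizes

The test suite and the acceptance script use the study-shaped data (26
channels, 75 time points, 20 samples per class) throughout; simulations run
on the 294-neuron desk grid, with the full 1200-neuron default reservoir used
where a single training run suffices. These sizes were chosen so the whole
suite completes in a few minutes on one CPU while keeping every statistical
check at the stated sample sizes.

## Known limitations

* The synthetic generator only plants amplitude effects; latency, coherence
  or spectral-shape effects are untested.
* Cluster membership far from the active core is geometric (nearest-input
  fallback), not spike-driven, whenever activity does not reach a region.
* The silhouette uses outgoing connections only; with the symmetric-ish
  random topology this is immaterial, but a strongly asymmetric learned graph
  would make the direction choice visible.
* Rule order grouping (integer division of baselines by `ℒ`) is one of
  several defensible coincidence definitions; the grouping window is
  configurable.
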
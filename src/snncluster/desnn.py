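"""Dynamic evolving SNN (deSNN) classification with rank-order learning.

One output neuron is created per training sample.  Its weight vector over the
reservoir neurons is initialised by the rank-order rule — the i-th reservoir
neuron to fire first gets weight mod**rank (rank 0 for the earliest spike, so
the first spike carries the largest weight) — and then adapted by a small
drift: +drift for every further spike of that neuron, -drift for every silent
step after its first spike, floored at 0.  A test sample is replayed through
the frozen reservoir, its weight vector built the same way, and classified by
the nearest training output neuron (Euclidean distance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import SampleSet
from .encoding import SpikeRaster, auto_thresholds, encode_samples
from .reservoir import (
    DEFAULT_INPUT_GAIN,
    LIFParams,
    ReservoirModel,
    STDPParams,
    init_reservoir,
    replay,
    train_unsupervised,
)

__all__ = ["DeSNNParams", "OutputNeuron", "train_desnn", "classify", "loocv", "LOOCVResult"]


@dataclass
class DeSNNParams:
    """mod is the rank-order modulation factor.  A value near 1 makes the
    weight vector reflect which neurons participated in a sample (their spike
    counts and presence) rather than the exact order of first spikes, which
    for oscillatory inputs with random phase is arbitrary."""

    mod: float = 0.995
    drift: float = 0.005
    distance: str = "euclidean"

    def __post_init__(self) -> None:
        if not 0.0 < self.mod < 1.0:
            raise ValueError("mod must lie strictly inside (0, 1)")
        if self.drift < 0:
            raise ValueError("drift must be >= 0")
        if self.distance != "euclidean":
            raise ValueError("only euclidean distance is supported")


@dataclass
class OutputNeuron:
    """One output neuron: the weight fingerprint of one sample's replay."""

    sample_id: int
    class_label: int
    W: np.ndarray
    psp: float = 0.0
    degenerate: bool = False  # sample produced no reservoir spikes


def output_neuron_from_history(
    fired_hist: np.ndarray,
    params: DeSNNParams,
    sample_id: int = -1,
    class_label: int = -1,
) -> OutputNeuron:
    """Build an output neuron from a (T, N) replay fired history.

    Spiking neurons are ranked by first-spike time (ties break to the lower
    neuron index) and initialised to mod**rank; drift adaptation then adds
    drift per extra spike and subtracts drift per silent step after the first
    spike, with a floor at 0.  Neurons that never spike keep weight 0.
    """
    fired_hist = np.asarray(fired_hist, dtype=bool)
    T, n = fired_hist.shape
    W = np.zeros(n)
    spiked = fired_hist.any(axis=0)
    if not spiked.any():
        warnings.warn(f"sample {sample_id} produced no reservoir spikes")
        return OutputNeuron(sample_id, class_label, W, psp=0.0, degenerate=True)
    first = np.where(spiked, fired_hist.argmax(axis=0), T)
    idx = np.nonzero(spiked)[0]
    order = idx[np.lexsort((idx, first[idx]))]  # by first-spike time, then index
    W[order] = params.mod ** np.arange(len(order))
    counts = fired_hist.sum(axis=0)
    extra = np.where(spiked, counts - 1, 0)
    silent = np.where(spiked, (T - 1 - first) - extra, 0)
    W = np.maximum(W + params.drift * (extra - silent), 0.0)
    return OutputNeuron(sample_id, class_label, W, psp=float(W.sum()))


def train_desnn(
    model: ReservoirModel,
    rasters: list[SpikeRaster],
    labels: np.ndarray,
    params: DeSNNParams | None = None,
    lif: LIFParams | None = None,
    input_gain: float = DEFAULT_INPUT_GAIN,
) -> list[OutputNeuron]:
    """Supervised phase: one rank-order output neuron per labelled sample.

    The reservoir must already be trained (its weights are frozen here); each
    sample is replayed through it to collect spike orders and counts.
    """
    params = params or DeSNNParams()
    if len(rasters) != len(labels):
        raise ValueError("rasters and labels lengths differ")
    return [
        output_neuron_from_history(
            replay(model, r, lif=lif, input_gain=input_gain),
            params, sample_id=i, class_label=int(labels[i]),
        )
        for i, r in enumerate(rasters)
    ]


def classify(
    output_neurons: list[OutputNeuron],
    test_raster: SpikeRaster,
    model: ReservoirModel,
    params: DeSNNParams | None = None,
    lif: LIFParams | None = None,
    input_gain: float = DEFAULT_INPUT_GAIN,
) -> int:
    """Predict the class of a test sample by the nearest output neuron."""
    params = params or DeSNNParams()
    if not output_neurons:
        raise ValueError("no trained output neurons")
    test = output_neuron_from_history(
        replay(model, test_raster, lif=lif, input_gain=input_gain), params
    )
    return classify_vector(output_neurons, test.W)


def classify_vector(output_neurons: list[OutputNeuron], W: np.ndarray) -> int:
    train_W = np.stack([o.W for o in output_neurons])
    d = np.linalg.norm(train_W - W[None, :], axis=1)
    return output_neurons[int(np.argmin(d))].class_label


@dataclass
class LOOCVResult:
    predictions: np.ndarray
    truths: np.ndarray
    accuracy: float
    confusion: pd.DataFrame

    @property
    def n_folds(self) -> int:
        return len(self.predictions)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "n_folds": self.n_folds,
            "predictions": self.predictions.tolist(),
            "truths": self.truths.tolist(),
            "confusion": {
                str(k): {str(c): int(x) for c, x in row.items()}
                for k, row in self.confusion.to_dict(orient="index").items()
            },
        }


def loocv(
    sample_set: SampleSet,
    grid: tuple[int, int, int] = (6, 6, 6),
    radius: float | None = None,
    seed: int = 0,
    lif: LIFParams | None = None,
    stdp: STDPParams | None = None,
    desnn_params: DeSNNParams | None = None,
    encode_threshold: float | np.ndarray | str = "auto",
    input_gain: float = DEFAULT_INPUT_GAIN,
    shared_reservoir: bool = False,
    montage=None,
) -> LOOCVResult:
    """Leave-one-out cross-validation of the full deSNN pipeline.

    By default each fold re-runs the unsupervised STDP phase on the training
    samples only (leak-free).  ``shared_reservoir=True`` trains the reservoir
    once on all samples — the protocol typical of streaming-SNN studies —
    which is much faster because every sample's replay can be reused across
    folds; the unsupervised phase never sees labels either way.
    """
    if sample_set.n_samples < 2:
        raise ValueError("LOOCV needs at least 2 samples")
    desnn_params = desnn_params or DeSNNParams()
    lif = lif or LIFParams()
    n = sample_set.n_samples
    labels = sample_set.labels
    preds = np.zeros(n, dtype=int)

    if shared_reservoir:
        rasters = encode_samples(sample_set, encode_threshold)
        model = init_reservoir(grid, montage, radius, seed, sample_set.channel_names)
        train_unsupervised(
            model, rasters, lif=lif, stdp=stdp, snapshot_every=10**9,
            input_gain=input_gain,
        )
        neurons = train_desnn(model, rasters, labels, desnn_params, lif, input_gain)
        for i in range(n):
            train_neurons = [o for o in neurons if o.sample_id != i]
            preds[i] = classify_vector(train_neurons, neurons[i].W)
    else:
        for i in range(n):
            keep = [j for j in range(n) if j != i]
            train_set = SampleSet(
                [sample_set.samples[j] for j in keep],
                labels[keep],
                sample_set.channel_names,
            )
            thr = encode_threshold
            if isinstance(thr, str) and thr == "auto":
                thr = auto_thresholds(train_set)
            train_rasters = encode_samples(train_set, thr)
            model = init_reservoir(grid, montage, radius, seed, sample_set.channel_names)
            train_unsupervised(
                model, train_rasters, lif=lif, stdp=stdp, snapshot_every=10**9,
                input_gain=input_gain,
            )
            neurons = train_desnn(model, train_rasters, labels[keep], desnn_params, lif, input_gain)
            from .encoding import encode

            test_raster = encode(sample_set.samples[i], thr)
            preds[i] = classify(neurons, test_raster, model, desnn_params, lif, input_gain)

    classes = np.unique(labels)
    conf = pd.DataFrame(0, index=classes, columns=classes)
    for t, p in zip(labels, preds):
        conf.loc[t, p] += 1
    return LOOCVResult(
        predictions=preds,
        truths=labels.copy(),
        accuracy=float((preds == labels).mean()),
        confusion=conf,
    )
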
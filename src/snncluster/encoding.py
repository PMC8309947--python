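"""Threshold-based temporal-contrast spike encoding.

Real-valued multichannel signals are turned into signed spike rasters: a
positive (excitatory) spike where the signal rises by more than a threshold
between consecutive time points, a negative (inhibitory) spike where it falls
by more than the threshold, and no event otherwise.  The first time point
carries no event (no difference is defined there).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .data import SampleSet

__all__ = ["SpikeRaster", "encode", "auto_thresholds", "encode_samples"]

#: "auto" threshold = this fraction of the SD of each channel's first differences.
AUTO_THRESHOLD_FRACTION = 0.5


@dataclass
class SpikeRaster:
    """Channels-by-time matrix of spike events in {-1, 0, +1}."""

    events: np.ndarray
    threshold_used: np.ndarray

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=np.int8)
        self.threshold_used = np.atleast_1d(np.asarray(self.threshold_used, dtype=float))
        if not np.isin(self.events, (-1, 0, 1)).all():
            raise ValueError("raster events must be in {-1, 0, +1}")
        if np.any(self.events[:, 0] != 0):
            raise ValueError("first time point must carry no events")
        if np.any(self.threshold_used < 0):
            raise ValueError("thresholds must be >= 0")

    @property
    def n_channels(self) -> int:
        return self.events.shape[0]

    @property
    def n_times(self) -> int:
        return self.events.shape[1]

    def to_hdf5(self, path: str | Path, key: str = "raster") -> None:
        with h5py.File(path, "a") as f:
            g = f.require_group(key)
            for name in ("events", "threshold_used"):
                if name in g:
                    del g[name]
            g.create_dataset("events", data=self.events, dtype="int8")
            g.create_dataset("threshold_used", data=self.threshold_used)

    @classmethod
    def from_hdf5(cls, path: str | Path, key: str = "raster") -> "SpikeRaster":
        with h5py.File(path, "r") as f:
            g = f[key]
            return cls(np.asarray(g["events"]), np.asarray(g["threshold_used"]))

    def to_event_csv(self, path: str | Path) -> None:
        """Event-list CSV with columns ``channel,time,polarity``."""
        ch, t = np.nonzero(self.events)
        pd.DataFrame(
            {"channel": ch, "time": t, "polarity": self.events[ch, t]}
        ).to_csv(path, index=False)


def encode(signal: np.ndarray, threshold: float | np.ndarray | str = "auto") -> SpikeRaster:
    """Encode a channels-by-time signal into a signed spike raster.

    For t >= 2 a channel fires +1 if the first difference exceeds its
    threshold, -1 if it falls below the negated threshold (strict
    inequalities; equality does not fire, so a flat signal at threshold 0
    stays silent).  ``threshold`` may be a scalar, a per-channel array, or
    ``"auto"`` (half the per-channel SD of first differences).
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 2:
        raise ValueError("signal must be a channels-by-time matrix")
    if not np.all(np.isfinite(signal)):
        raise ValueError("signal must be finite")
    diffs = np.diff(signal, axis=1)
    if isinstance(threshold, str):
        if threshold != "auto":
            raise ValueError(f"unknown threshold mode {threshold!r}")
        theta = AUTO_THRESHOLD_FRACTION * diffs.std(axis=1)
    else:
        theta = np.broadcast_to(
            np.asarray(threshold, dtype=float), (signal.shape[0],)
        ).copy()
        if np.any(theta < 0):
            raise ValueError("threshold must be >= 0")
    events = np.zeros(signal.shape, dtype=np.int8)
    events[:, 1:] = (diffs > theta[:, None]).astype(np.int8) - (
        diffs < -theta[:, None]
    ).astype(np.int8)
    return SpikeRaster(events, theta)


def auto_thresholds(sample_set: SampleSet) -> np.ndarray:
    """Per-channel auto thresholds pooled over all samples of a set.

    Pooling keeps the threshold common to both classes, so genuine
    between-class amplitude differences survive encoding (a per-sample auto
    threshold would normalise them away).
    """
    diffs = np.concatenate([np.diff(s, axis=1) for s in sample_set.samples], axis=1)
    return AUTO_THRESHOLD_FRACTION * diffs.std(axis=1)


def encode_samples(
    sample_set: SampleSet, threshold: float | np.ndarray | str = "auto"
) -> list[SpikeRaster]:
    """Encode every sample; ``"auto"`` uses set-pooled per-channel thresholds."""
    if isinstance(threshold, str) and threshold == "auto":
        threshold = auto_thresholds(sample_set)
    return [encode(s, threshold) for s in sample_set.samples]
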
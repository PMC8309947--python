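"""Data containers, montage handling, file I/O and synthetic EEG-like data.

The package operates on sets of channel-by-time matrices (one matrix per
recording sample, e.g. one EEG epoch) with an integer class label per sample,
plus a montage mapping channel names to 3-D head coordinates.  Since suitable
clinical EEG is rarely shareable, :func:`generate_dataset` produces a
synthetic two-class stand-in with the same shape: 26 channels of noisy
sinusoids, 75 time points per sample, with a chosen subset of channels
carrying a class-discriminative amplitude difference.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "SampleSet",
    "Montage",
    "default_montage",
    "read_montage",
    "write_montage",
    "read_samples",
    "write_samples",
    "generate_dataset",
    "EEG_1020_CHANNELS",
]

# The 26 scalp electrodes of the extended 10-20 montage used throughout,
# in canonical order (this order defines channel/cluster indices 1..26).
EEG_1020_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "Fz", "F3", "F4", "F7", "F8", "Cz", "C3", "C4",
    "CP3", "CPz", "CP4", "FC3", "FCz", "FC4", "T3", "T4", "T5", "T6",
    "Pz", "P3", "P4", "O1", "O2", "Oz",
)

# Approximate 10-20 electrode positions as spherical angles on a unit head:
# (inclination from the vertex, azimuth from the anterior midline, degrees;
# azimuth positive toward the right ear).  T3/T4/T5/T6 are the classic names
# for T7/T8/P7/P8.
_ELECTRODE_ANGLES: dict[str, tuple[float, float]] = {
    "Cz": (0.0, 0.0),
    "FCz": (23.0, 0.0), "Fz": (45.0, 0.0),
    "CPz": (23.0, 180.0), "Pz": (45.0, 180.0),
    "C3": (45.0, -90.0), "C4": (45.0, 90.0),
    "F3": (60.0, -39.0), "F4": (60.0, 39.0),
    "P3": (60.0, -141.0), "P4": (60.0, 141.0),
    "FC3": (49.0, -55.0), "FC4": (49.0, 55.0),
    "CP3": (49.0, -125.0), "CP4": (49.0, 125.0),
    "Fp1": (90.0, -18.0), "Fp2": (90.0, 18.0),
    "F7": (90.0, -54.0), "F8": (90.0, 54.0),
    "T3": (90.0, -90.0), "T4": (90.0, 90.0),
    "T5": (90.0, -126.0), "T6": (90.0, 126.0),
    "O1": (90.0, -162.0), "O2": (90.0, 162.0),
    "Oz": (90.0, 180.0),
}


@dataclass
class Montage:
    """Channel name -> (x, y, z) coordinates in a consistent 3-D head frame."""

    entries: dict[str, tuple[float, float, float]]

    def __post_init__(self) -> None:
        if len(self.entries) == 0:
            raise ValueError("montage must contain at least one channel")
        for name, xyz in self.entries.items():
            if len(xyz) != 3 or not all(math.isfinite(c) for c in xyz):
                raise ValueError(f"non-finite coordinates for channel {name!r}")

    @property
    def channel_names(self) -> list[str]:
        return list(self.entries)

    def coordinates(self, channel_names: Sequence[str] | None = None) -> np.ndarray:
        """Coordinate array (n_channels, 3) in the given (or native) order."""
        names = self.channel_names if channel_names is None else list(channel_names)
        missing = [n for n in names if n not in self.entries]
        if missing:
            raise KeyError(f"channels not in montage: {missing}")
        return np.array([self.entries[n] for n in names], dtype=float)


def default_montage() -> Montage:
    """The bundled 26-electrode 10-20 montage on a unit-sphere head model."""
    entries = {}
    for name in EEG_1020_CHANNELS:
        inc, az = _ELECTRODE_ANGLES[name]
        inc, az = math.radians(inc), math.radians(az)
        x = math.sin(inc) * math.sin(az)
        y = math.sin(inc) * math.cos(az)
        z = math.cos(inc)
        entries[name] = (x, y, z)
    return Montage(entries)


def synthetic_montage(channel_names: Sequence[str]) -> Montage:
    """Evenly spread coordinates for channels without 10-20 names.

    Places the channels on the upper unit hemisphere along a Fibonacci
    lattice — deterministic, distinct, and roughly head-like — so reservoirs
    can be built over arbitrary channel sets.
    """
    names = list(channel_names)
    k = len(names)
    golden = (1 + 5**0.5) / 2
    entries = {}
    for i, name in enumerate(names):
        z = (i + 0.5) / k  # upper hemisphere only
        r = math.sqrt(max(1.0 - z * z, 0.0))
        az = 2 * math.pi * i / golden
        entries[name] = (r * math.cos(az), r * math.sin(az), z)
    return Montage(entries)


def read_montage(path: str | Path) -> Montage:
    """Read a montage from TSV with columns ``name, x, y, z``."""
    df = pd.read_csv(path, sep="\t")
    if df["name"].duplicated().any():
        raise ValueError("duplicate channel names in montage file")
    entries = {
        str(r["name"]): (float(r["x"]), float(r["y"]), float(r["z"]))
        for _, r in df.iterrows()
    }
    return Montage(entries)


def write_montage(montage: Montage, path: str | Path) -> None:
    rows = [(n, *xyz) for n, xyz in montage.entries.items()]
    pd.DataFrame(rows, columns=["name", "x", "y", "z"]).to_csv(
        path, sep="\t", index=False
    )


@dataclass
class SampleSet:
    """A labelled collection of channel-by-time matrices.

    All samples share the channel count and ordering given by
    ``channel_names``; time lengths may differ between samples (they do not
    in the bundled generator).  Labels are small positive integers (1..k).
    """

    samples: list[np.ndarray]
    labels: np.ndarray
    channel_names: list[str]
    sampling_note: str = ""

    def __post_init__(self) -> None:
        self.samples = [np.asarray(s, dtype=float) for s in self.samples]
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.samples):
            raise ValueError("labels length must equal number of samples")
        v = len(self.channel_names)
        for i, s in enumerate(self.samples):
            if s.ndim != 2 or s.shape[0] != v:
                raise ValueError(
                    f"sample {i} has shape {s.shape}; expected ({v}, time)"
                )
            if not np.all(np.isfinite(s)):
                raise ValueError(f"sample {i} contains non-finite values")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)


# ---------------------------------------------------------------------------
# File I/O.  CSV layout: one file per sample, channels as rows, a leading
# `channel` column of channel names; sidecar labels.csv with sample_id,label.
# HDF5 layout: one group per sample with dataset `data` and attr `label`;
# channel names stored as a root attribute.
# ---------------------------------------------------------------------------

def write_samples(sample_set: SampleSet, path: str | Path, format: str = "csv-dir") -> None:
    path = Path(path)
    if format == "csv-dir":
        path.mkdir(parents=True, exist_ok=True)
        ids = []
        for i, s in enumerate(sample_set.samples):
            df = pd.DataFrame(s, index=pd.Index(sample_set.channel_names, name="channel"))
            df.columns = [f"t{j}" for j in range(s.shape[1])]
            sid = f"sample_{i:04d}"
            df.to_csv(path / f"{sid}.csv", float_format="%.17g")
            ids.append(sid)
        pd.DataFrame({"sample_id": ids, "label": sample_set.labels}).to_csv(
            path / "labels.csv", index=False
        )
    elif format == "hdf5":
        with h5py.File(path, "w") as f:
            f.attrs["channel_names"] = list(sample_set.channel_names)
            f.attrs["sampling_note"] = sample_set.sampling_note
            for i, s in enumerate(sample_set.samples):
                g = f.create_group(f"sample_{i:04d}")
                g.create_dataset("data", data=s)
                g.attrs["label"] = int(sample_set.labels[i])
    else:
        raise ValueError(f"unknown format {format!r}")


def read_samples(path: str | Path, format: str = "csv-dir") -> SampleSet:
    """Read a :class:`SampleSet` written by :func:`write_samples`.

    Raises ``ValueError`` on ragged channel counts or non-numeric cells.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "csv-dir":
        labels_df = pd.read_csv(path / "labels.csv")
        samples, channel_names = [], None
        for sid in labels_df["sample_id"]:
            try:
                df = pd.read_csv(
                    path / f"{sid}.csv", index_col="channel",
                    float_precision="round_trip",
                )
                mat = df.to_numpy(dtype=float)
            except (ValueError, TypeError) as e:
                raise ValueError(f"non-numeric data in {sid}.csv: {e}") from e
            names = [str(n) for n in df.index]
            if channel_names is None:
                channel_names = names
            elif names != channel_names:
                raise ValueError(
                    f"{sid}.csv channel rows {names} do not match {channel_names}"
                )
            samples.append(mat)
        return SampleSet(samples, labels_df["label"].to_numpy(), channel_names)
    elif format == "hdf5":
        with h5py.File(path, "r") as f:
            channel_names = [str(n) for n in f.attrs["channel_names"]]
            note = str(f.attrs.get("sampling_note", ""))
            samples, labels = [], []
            for key in sorted(f.keys()):
                g = f[key]
                mat = np.asarray(g["data"], dtype=float)
                if mat.shape[0] != len(channel_names):
                    raise ValueError(
                        f"{key} has {mat.shape[0]} channels; expected {len(channel_names)}"
                    )
                samples.append(mat)
                labels.append(int(g.attrs["label"]))
        return SampleSet(samples, np.array(labels), channel_names, note)
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Synthetic generator
# ---------------------------------------------------------------------------

#: Default planted channels: the eight 10-20 electrodes most often reported as
#: discriminative in inhibition-task EEG (Fz, F4, C3, C4, CPz, T6, Pz, P4),
#: as 1-based indices into EEG_1020_CHANNELS.
DEFAULT_PLANTED: tuple[int, ...] = (3, 5, 9, 10, 12, 20, 21, 23)

_NOISE_SD = 0.5   # Gaussian noise SD, the amplitude unit of `effect`
_BASE_AMP = 1.0   # class-1 sinusoid amplitude


def generate_dataset(
    n_per_class: int = 20,
    v: int = 26,
    length: int = 75,
    planted: Iterable[int] = DEFAULT_PLANTED,
    effect: float = 2.0,
    seed: int = 0,
) -> SampleSet:
    """Generate a two-class synthetic multichannel set.

    Each channel carries a sinusoid (fixed per-channel frequency, random
    phase per sample) plus Gaussian noise of SD 0.5.  In class-2 samples the
    ``planted`` channels (1-based indices) are scaled by a whole-channel gain
    that raises the oscillatory amplitude by ``effect`` noise standard
    deviations — an amplitude (power) difference of the kind seen between
    subject groups in band-limited EEG, where the background scales with the
    oscillation.  All other channels are identically distributed across
    classes, so at ``effect=0`` the class labels are exchangeable.

    Deterministic for a fixed ``seed``.
    """
    if effect < 0:
        raise ValueError("effect must be >= 0")
    planted = sorted(set(int(p) for p in planted))
    if planted and (planted[0] < 1 or planted[-1] > v):
        raise ValueError(f"planted channels must lie in 1..{v}")
    planted0 = np.array([p - 1 for p in planted], dtype=int)

    if v == len(EEG_1020_CHANNELS):
        channel_names = list(EEG_1020_CHANNELS)
    else:
        channel_names = [f"ch{c + 1:02d}" for c in range(v)]

    rng = np.random.default_rng(seed)
    # fixed per-channel frequency: 2..8 cycles per window
    cycles = 2.0 + 6.0 * np.arange(v) / max(v - 1, 1)
    t = np.arange(length)

    gain = np.ones((2, v))
    if planted0.size:
        gain[1, planted0] = (_BASE_AMP + effect * _NOISE_SD) / _BASE_AMP

    samples, labels = [], []
    for cls in (1, 2):
        for _ in range(n_per_class):
            phase = rng.uniform(0.0, 2.0 * np.pi, size=v)
            sig = _BASE_AMP * np.sin(
                2.0 * np.pi * cycles[:, None] * t[None, :] / length + phase[:, None]
            )
            sig = gain[cls - 1][:, None] * (
                sig + rng.normal(0.0, _NOISE_SD, size=(v, length))
            )
            samples.append(sig)
            labels.append(cls)
    return SampleSet(
        samples,
        np.array(labels),
        channel_names,
        sampling_note=f"synthetic two-class set, effect={effect}, seed={seed}",
    )
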
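"""Connection-weight silhouette validity of the final clustering.

For each neuron i in cluster gamma, cohesion x(i) is the mean weight of its
connections to same-cluster neurons scaled by its membership value to its own
centre, and separation y(i) averages, over the f clusters adjacent to gamma,
the mean weight of i's connections into that cluster scaled by the membership
to that centre.  The silhouette is

    s(i) = (x(i) - y(i)) / max(x(i), y(i)),   s(i) in [-1, 1]

with s(i) = 0 when both terms vanish.  By default absolute weight values
enter the means, so mixed-sign weights cannot invert the cohesion semantics.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .clustering import cluster_adjacency
from .reservoir import ReservoirModel

__all__ = ["SilhouetteReport", "silhouette", "plot_silhouette"]


@dataclass
class SilhouetteReport:
    per_neuron: np.ndarray        # s(i)
    per_cluster_mean: np.ndarray  # mean s over members, per cluster
    x: np.ndarray                 # cohesion
    y: np.ndarray                 # separation
    labels: np.ndarray
    flagged: np.ndarray           # neurons with no connections (s forced to 0)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "neuron": np.arange(len(self.per_neuron)),
                "cluster": self.labels,
                "x": self.x,
                "y": self.y,
                "s": self.per_neuron,
            }
        ).to_csv(path, index=False)


def silhouette(
    model: ReservoirModel,
    labels: np.ndarray,
    F_star: np.ndarray,
    adjacency: list[tuple[int, int]] | None = None,
    use_abs_weights: bool = True,
) -> SilhouetteReport:
    """Membership-weighted silhouette of a clustering over the reservoir graph.

    ``adjacency`` lists the neighbouring cluster pairs (defaults to the
    montage-derived adjacency of the clustering module).  Connections are
    taken in the outgoing direction (w[i, j]).  Neurons with no connections
    are flagged and given s(i) = 0.
    """
    labels = np.asarray(labels, dtype=int)
    F_star = np.asarray(F_star, dtype=float)
    n, v = F_star.shape
    if adjacency is None:
        adjacency = cluster_adjacency(model.input_coords)
    neighbours: dict[int, list[int]] = {c: [] for c in range(v)}
    for a, b in adjacency:
        neighbours[a].append(b)
        neighbours[b].append(a)

    W = np.abs(model.w) if use_abs_weights else model.w.copy()
    W = np.where(model.connected, W, 0.0)
    onehot = np.zeros((n, v))
    onehot[np.arange(n), labels] = 1.0
    wsum = W @ onehot                                   # (N, v) weight sums into each cluster
    cnt = model.connected.astype(float) @ onehot        # (N, v) connection counts
    mean_w = np.divide(wsum, cnt, out=np.zeros_like(wsum), where=cnt > 0)

    x = mean_w[np.arange(n), labels] * F_star[np.arange(n), labels]
    y = np.zeros(n)
    for c in range(v):
        nbrs = neighbours[c]
        members = labels == c
        if not nbrs or not members.any():
            continue
        contrib = np.zeros(members.sum())
        for b in nbrs:
            contrib += mean_w[members, b] * F_star[members, b]
        y[members] = contrib / len(nbrs)

    denom = np.maximum(x, y)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(denom != 0, (x - y) / denom, 0.0)
    s = np.clip(s, -1.0, 1.0)
    flagged = ~model.connected.any(axis=1)
    s[flagged] = 0.0

    per_cluster = np.zeros(v)
    for c in range(v):
        members = labels == c
        if members.any():
            per_cluster[c] = s[members].mean()
    return SilhouetteReport(
        per_neuron=s, per_cluster_mean=per_cluster, x=x, y=y,
        labels=labels, flagged=flagged,
    )


def plot_silhouette(report: SilhouetteReport, channel_names: list[str] | None = None, ax=None):
    """Bar chart of per-cluster mean silhouette values."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    v = len(report.per_cluster_mean)
    xticks = channel_names if channel_names is not None else [str(c) for c in range(v)]
    ax.bar(np.arange(v), report.per_cluster_mean)
    ax.set_xticks(np.arange(v), xticks, rotation=90, fontsize=7)
    ax.set_ylabel("mean silhouette s(i)")
    ax.set_ylim(-1, 1)
    return ax
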
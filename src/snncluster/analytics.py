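"""Per-cluster dynamic traces and PSP-based feature selection.

While the reservoir learns, each cluster (one per input channel) is tracked
through five time series: the centre channel's input spike train, the mean
membrane potential of its member neurons (the cluster PSP, muPSP(t)), the
members' mean spiking rate, the cluster size and the members' mean membership
value.  Per sample, the muPSP segment is condensed into three scalars — the
local maximum Pmax, the area under the curve and the midrange (max+min)/2 —
and a two-sample Welch t-test on any of the three ranks the channels by how
well they separate the classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import ClusterFrame
from .encoding import SpikeRaster
from .reservoir import ReservoirModel, TrainLog

__all__ = [
    "ClusterTrace",
    "PSPSummary",
    "compute_traces",
    "summarize_psp",
    "psp_summaries",
    "select_features",
]

_STATISTICS = ("p_max", "area", "midrange")


@dataclass
class ClusterTrace:
    """Five per-time-point series describing one cluster's evolution.

    Frame-level quantities (size, mean membership) are held constant between
    clustering snapshots so all series share the streamed time axis.
    """

    cluster_id: int
    st: np.ndarray               # input spike train of the centre channel
    mu_psp: np.ndarray           # mean member membrane potential
    sr: np.ndarray               # mean member spiking rate
    size: np.ndarray             # member count (frame-current)
    mean_membership: np.ndarray  # mean member F* column value (frame-current)


def _frame_of_step(frames: list[ClusterFrame], n_steps: int) -> np.ndarray:
    """Index of the latest frame at or before each streamed step."""
    times = np.array([f.t for f in frames])
    return np.searchsorted(times, np.arange(n_steps), side="right") - 1


def compute_traces(
    model: ReservoirModel, log: TrainLog, rasters: list[SpikeRaster]
) -> list[ClusterTrace]:
    """One :class:`ClusterTrace` per cluster from a recorded training run.

    muPSP(t) is the arithmetic mean of the member neurons' (pre-reset)
    membrane potentials under the frame-current membership; a cluster with no
    members at some frame contributes zeros there.  Requires training with
    ``record=True``.
    """
    if log.v_hist is None or log.fire_hist is None:
        raise ValueError("training was run without per-step recording")
    v = model.n_inputs
    T = log.streamed_points
    st_all = np.concatenate([r.events for r in rasters], axis=1)
    if st_all.shape[1] != T:
        raise ValueError("raster lengths do not match the streamed point count")

    fidx = _frame_of_step(log.frames, T)
    mu = np.zeros((T, v))
    sr = np.zeros((T, v))
    size = np.zeros((T, v), dtype=int)
    mm = np.zeros((T, v))
    for fi in np.unique(fidx):
        frame = log.frames[fi]
        steps = fidx == fi
        onehot = np.zeros((model.n_neurons, v))
        onehot[np.arange(model.n_neurons), frame.labels] = 1.0
        counts = onehot.sum(axis=0)
        safe = np.where(counts > 0, counts, 1.0)
        mu[steps] = (log.v_hist[steps] @ onehot) / safe
        sr[steps] = (log.fire_hist[steps] @ onehot) / safe
        size[steps] = counts.astype(int)
        mm[steps] = (frame.F_star * onehot).sum(axis=0) / safe
    return [
        ClusterTrace(
            cluster_id=j, st=st_all[j], mu_psp=mu[:, j], sr=sr[:, j],
            size=size[:, j], mean_membership=mm[:, j],
        )
        for j in range(v)
    ]


@dataclass
class PSPSummary:
    """Scalar summaries of one sample's muPSP segment for one cluster."""

    p_max: float
    t_of_max: int
    area: float
    midrange: float
    sample_id: int | None = None
    cluster_id: int | None = None
    class_label: int | None = None


def summarize_psp(
    segment: np.ndarray,
    rule: str = "rectangle",
    sample_id: int | None = None,
    cluster_id: int | None = None,
    class_label: int | None = None,
) -> PSPSummary:
    """Pmax, area under the curve and midrange of a muPSP segment.

    The area uses a unit-step rectangle sum by default (``rule="trapezoid"``
    switches to the trapezoidal rule).  A single-point segment has
    p_max = midrange = area = that value under the rectangle rule.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.ndim != 1 or segment.size == 0:
        raise ValueError("segment must be a nonempty 1-D series")
    if rule == "rectangle":
        area = float(segment.sum())
    elif rule == "trapezoid":
        area = float(np.trapezoid(segment))
    else:
        raise ValueError(f"unknown area rule {rule!r}")
    return PSPSummary(
        p_max=float(segment.max()),
        t_of_max=int(np.argmax(segment)),
        area=area,
        midrange=float((segment.max() + segment.min()) / 2.0),
        sample_id=sample_id,
        cluster_id=cluster_id,
        class_label=class_label,
    )


def psp_summaries(
    traces: list[ClusterTrace],
    sample_bounds: list[tuple[int, int]],
    labels: np.ndarray,
    rule: str = "rectangle",
) -> pd.DataFrame:
    """Per-(sample, cluster) PSP summaries as a tidy DataFrame."""
    rows = []
    for s, (start, end) in enumerate(sample_bounds):
        for tr in traces:
            summ = summarize_psp(
                tr.mu_psp[start:end], rule=rule,
                sample_id=s, cluster_id=tr.cluster_id, class_label=int(labels[s]),
            )
            rows.append(
                {
                    "sample": s,
                    "cluster": tr.cluster_id,
                    "class": int(labels[s]),
                    "p_max": summ.p_max,
                    "t_of_max": summ.t_of_max,
                    "area": summ.area,
                    "midrange": summ.midrange,
                }
            )
    return pd.DataFrame(rows)


def select_features(
    summaries: pd.DataFrame,
    statistic: str = "area",
    k_top: int = 8,
    mutual: bool = False,
) -> tuple[pd.DataFrame, list[int]]:
    """Rank channels by class separation of a PSP summary statistic.

    Runs a two-sample Welch t-test between the two classes on the chosen
    statistic, per cluster/channel, and ranks channels by ascending p-value.
    With ``mutual=True`` the returned top list is the intersection of the
    top-``k_top`` sets under all three statistics (ordered by the requested
    statistic's rank).

    Returns ``(ranking, top_channels)`` where ``ranking`` has one row per
    (channel, statistic) with columns ``channel, statistic, p_value, rank``.
    """
    if statistic not in _STATISTICS:
        raise ValueError(f"statistic must be one of {_STATISTICS}")
    classes = np.sort(summaries["class"].unique())
    if len(classes) != 2:
        raise ValueError("feature selection requires exactly two classes")
    for cls in classes:
        if summaries.loc[summaries["class"] == cls, "sample"].nunique() < 2:
            raise ValueError(f"class {cls} has fewer than 2 samples")

    stats_needed = _STATISTICS if mutual else (statistic,)
    frames = []
    for stat in stats_needed:
        rows = []
        for ch, grp in summaries.groupby("cluster"):
            a = grp.loc[grp["class"] == classes[0], stat].to_numpy()
            b = grp.loc[grp["class"] == classes[1], stat].to_numpy()
            t, p = stats.ttest_ind(a, b, equal_var=False)
            rows.append({"channel": int(ch), "statistic": stat, "p_value": float(p)})
        df = pd.DataFrame(rows).sort_values("p_value", kind="stable")
        df["rank"] = np.arange(1, len(df) + 1)
        # ranking uses raw p-values; BH-adjusted values reported alongside
        df["q_value"] = stats.false_discovery_control(df["p_value"], method="bh")
        frames.append(df)
    ranking = pd.concat(frames, ignore_index=True)

    primary = ranking[ranking["statistic"] == statistic]
    top = primary.nsmallest(k_top, "rank")["channel"].tolist()
    if mutual:
        keep = set(top)
        for stat in _STATISTICS:
            sub = ranking[ranking["statistic"] == stat]
            keep &= set(sub.nsmallest(k_top, "rank")["channel"])
        top = [ch for ch in top if ch in keep]
    return ranking, top
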
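"""Dynamic spreading-activation clustering of reservoir neurons.

Neurons are clustered around the input neurons (one per data channel) by
spreading "information" over the spike-transmission graph.  The transmitted
spike counts A are symmetrised into an affinity A', normalised into S, and
the membership matrix is the steady state of label spreading from the input
neurons:

    F* = (I - alpha*S)^(-1) Fsrc,   alpha in (0, 1)

Each neuron takes the cluster label of the input column holding its largest
membership.  Because clustering is recomputed as learning streams, a neuron's
label can churn between adjacent clusters over time; the set of neurons a
pair of clusters exchanged defines their fuzzy boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "ClusterFrame",
    "FuzzyBoundary",
    "symmetrize_affinity",
    "propagate",
    "assign",
    "fuzzy_boundaries",
    "cluster_adjacency",
    "write_frame_log",
    "read_frame_log",
]


@dataclass
class ClusterFrame:
    """One clustering snapshot: memberships, labels and cluster sizes.

    ``labels`` are 0-based column indices into F_star; ``flagged`` marks
    neurons assigned by the nearest-input fallback (all-zero membership row).
    """

    t: int
    F_star: np.ndarray
    labels: np.ndarray
    sizes: np.ndarray
    flagged: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.F_star = np.asarray(self.F_star, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.sizes = np.asarray(self.sizes, dtype=int)
        if self.flagged is None:
            self.flagged = np.zeros(len(self.labels), dtype=bool)
        n, v = self.F_star.shape
        if self.sizes.sum() != n:
            raise ValueError("cluster sizes must sum to the neuron count")
        if len(self.sizes) != v:
            raise ValueError("sizes length must equal the number of clusters")


@dataclass
class FuzzyBoundary:
    """Neurons exchanged between two clusters across learning frames."""

    pair: tuple[int, int]
    shared_neurons: frozenset[int]

    def __post_init__(self) -> None:
        a, b = self.pair
        if a == b:
            raise ValueError("boundary requires two distinct clusters")
        self.pair = (min(a, b), max(a, b))
        self.shared_neurons = frozenset(self.shared_neurons)

    @property
    def size(self) -> int:
        return len(self.shared_neurons)


def symmetrize_affinity(spike_log) -> np.ndarray | sparse.csr_matrix:
    """A'[i,j] = A[i,j] + A[j,i] off-diagonal, 0 on the diagonal.

    Accepts a dense array or a scipy sparse matrix (large reservoirs have
    sparse spike graphs) and returns the same kind.
    """
    if sparse.issparse(spike_log):
        A = spike_log.tocsr().astype(float)
        if A.nnz and A.data.min() < 0:
            raise ValueError("spike counts must be nonnegative")
        A_prime = A + A.T
        A_prime.setdiag(0.0)
        A_prime.eliminate_zeros()
        return A_prime
    A = np.asarray(spike_log, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("spike_log must be square")
    if np.any(A < 0):
        raise ValueError("spike counts must be nonnegative")
    A_prime = A + A.T
    np.fill_diagonal(A_prime, 0.0)
    return A_prime


def _normalized_affinity(A_prime, normalization: str):
    """S = D A' D.  Default D_ii = 1/sqrt(T_i) (symmetric normalisation, which
    bounds the spectral radius of S by 1 so alpha*S is a contraction for
    alpha < 1); ``"inverse"`` uses the literal D_ii = 1/T_i.  Isolated neurons
    (T_i = 0) get D_ii = 0."""
    T = np.asarray(A_prime.sum(axis=1)).ravel()
    with np.errstate(divide="ignore"):
        if normalization == "sqrt":
            d = np.where(T > 0, 1.0 / np.sqrt(T), 0.0)
        elif normalization == "inverse":
            d = np.where(T > 0, 1.0 / T, 0.0)
        else:
            raise ValueError(f"unknown normalization {normalization!r}")
    if sparse.issparse(A_prime):
        D = sparse.diags(d)
        return (D @ A_prime @ D).tocsr()
    return A_prime * d[:, None] * d[None, :]


def propagate(
    A_prime: np.ndarray,
    Fsrc: np.ndarray,
    alpha: float = 0.9,
    mode: str = "closed_form",
    tol: float = 1e-10,
    normalization: str = "sqrt",
    F0: np.ndarray | None = None,
    max_iter: int = 100_000,
) -> np.ndarray:
    """Steady-state membership matrix F* of spreading activation.

    ``closed_form`` solves (I - alpha*S) F* = Fsrc directly.  ``iterative``
    runs F(t+1) = alpha*S*F(t) + (1-alpha)*Fsrc from F(0) = Fsrc (or a warm
    start ``F0`` on the F* scale) until the largest entry change is below
    ``tol``; the converged iterate is rescaled by 1/(1-alpha) so that both
    modes return the same matrix, which reduces to F* = Fsrc exactly when
    A' = 0.  The rescaling does not affect the argmax labels.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie strictly inside (0, 1)")
    if not sparse.issparse(A_prime):
        A_prime = np.asarray(A_prime, dtype=float)
    Fsrc = np.asarray(Fsrc, dtype=float)
    if A_prime.shape[0] != Fsrc.shape[0]:
        raise ValueError("A_prime and Fsrc row counts differ")
    S = _normalized_affinity(A_prime, normalization)

    if mode == "closed_form":
        if sparse.issparse(S):
            lhs = sparse.eye(S.shape[0], format="csc") - alpha * S
            F_star = sparse.linalg.spsolve(lhs, sparse.csc_matrix(Fsrc)).toarray()
        else:
            lhs = np.eye(S.shape[0]) - alpha * S
            F_star = np.linalg.solve(lhs, Fsrc)
        assert np.all(np.isfinite(F_star)), "propagation system unexpectedly singular"
        return F_star
    elif mode == "iterative":
        F = Fsrc.copy() if F0 is None else (1.0 - alpha) * np.asarray(F0, dtype=float)
        source = (1.0 - alpha) * Fsrc
        # contraction bound: after rescaling by 1/(1-alpha), the F* error is at
        # most alpha/(1-alpha)^2 times the last iterate change, so stop early
        # enough that the returned matrix is within tol of the closed form
        step_tol = tol * (1.0 - alpha) ** 2 / alpha
        for _ in range(max_iter):
            F_new = alpha * (S @ F) + source
            if np.max(np.abs(F_new - F)) < step_tol:
                F = F_new
                break
            F = F_new
        else:
            raise RuntimeError("iterative propagation did not converge")
        return F / (1.0 - alpha)
    raise ValueError(f"unknown mode {mode!r}")


def assign(
    F_star: np.ndarray,
    coords: np.ndarray | None = None,
    input_neurons: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-neuron cluster labels from the membership matrix.

    Labels are the per-row argmax (ties break to the lowest column index).
    All-zero rows carry no information; when ``coords`` and the input-neuron
    indices are given, such neurons fall back to the cluster of the nearest
    input neuron and are flagged.

    Returns ``(labels, sizes, flagged)`` with 0-based labels.
    """
    F_star = np.asarray(F_star, dtype=float)
    if F_star.ndim != 2 or F_star.shape[1] < 1:
        raise ValueError("F_star must have at least one column")
    n, v = F_star.shape
    labels = np.argmax(F_star, axis=1)  # argmax takes the first (lowest) index on ties
    flagged = ~F_star.any(axis=1)
    if flagged.any() and coords is not None and input_neurons is not None:
        input_neurons = np.asarray(input_neurons, dtype=int)
        zero_idx = np.nonzero(flagged)[0]
        d = np.linalg.norm(
            coords[zero_idx][:, None, :] - coords[input_neurons][None, :, :], axis=2
        )
        labels[zero_idx] = np.argmin(d, axis=1)
    sizes = np.bincount(labels, minlength=v)
    return labels, sizes, flagged


def cluster_adjacency(
    input_coords: np.ndarray, factor: float = 2.0
) -> list[tuple[int, int]]:
    """Cluster pairs whose centres lie within ``factor`` times the median
    nearest-neighbour distance between input neurons (0-based indices)."""
    input_coords = np.asarray(input_coords, dtype=float)
    v = input_coords.shape[0]
    d = np.linalg.norm(input_coords[:, None, :] - input_coords[None, :, :], axis=2)
    np.fill_diagonal(d, np.inf)
    cutoff = factor * np.median(d.min(axis=1))
    return [(a, b) for a in range(v) for b in range(a + 1, v) if d[a, b] <= cutoff]


def fuzzy_boundaries(
    frames: list[ClusterFrame],
    adjacency: list[tuple[int, int]] | None = None,
) -> list[FuzzyBoundary]:
    """Boundaries of neurons exchanged between cluster pairs across frames.

    A neuron belongs to boundary (a, b) iff its label is a in some frame and
    b in another.  ``adjacency`` restricts reporting to the given cluster
    pairs (e.g. montage-adjacent clusters); by default all pairs with a
    nonempty boundary are reported.  Sorted by boundary size descending.
    """
    if len(frames) < 2:
        warnings.warn("fuzzy boundaries need at least two frames; returning none")
        return []
    history = np.stack([f.labels for f in frames], axis=1)  # (N, n_frames)
    n, _ = history.shape
    shared: dict[tuple[int, int], set[int]] = {}
    for i in range(n):
        visited = sorted(set(history[i].tolist()))
        for ai in range(len(visited)):
            for bi in range(ai + 1, len(visited)):
                shared.setdefault((visited[ai], visited[bi]), set()).add(i)
    if adjacency is not None:
        allowed = {(min(a, b), max(a, b)) for a, b in adjacency}
        shared = {p: s for p, s in shared.items() if p in allowed}
    out = [FuzzyBoundary(pair, frozenset(s)) for pair, s in shared.items()]
    out.sort(key=lambda b: (-b.size, b.pair))
    return out


def boundary_report(boundaries: list[FuzzyBoundary], path: str | Path) -> None:
    """Boundary CSV with columns ``cluster_a,cluster_b,size,neuron_ids``."""
    rows = [
        {
            "cluster_a": b.pair[0],
            "cluster_b": b.pair[1],
            "size": b.size,
            "neuron_ids": " ".join(str(i) for i in sorted(b.shared_neurons)),
        }
        for b in boundaries
    ]
    pd.DataFrame(rows, columns=["cluster_a", "cluster_b", "size", "neuron_ids"]).to_csv(
        path, index=False
    )


def write_frame_log(frames: list[ClusterFrame], path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        for i, fr in enumerate(frames):
            g = f.create_group(f"frame_{i:05d}")
            g.attrs["t"] = fr.t
            g.create_dataset("F_star", data=fr.F_star)
            g.create_dataset("labels", data=fr.labels)
            g.create_dataset("sizes", data=fr.sizes)
            g.create_dataset("flagged", data=fr.flagged)


def read_frame_log(path: str | Path) -> list[ClusterFrame]:
    frames = []
    with h5py.File(path, "r") as f:
        for key in sorted(f.keys()):
            g = f[key]
            frames.append(
                ClusterFrame(
                    t=int(g.attrs["t"]),
                    F_star=np.asarray(g["F_star"]),
                    labels=np.asarray(g["labels"]),
                    sizes=np.asarray(g["sizes"]),
                    flagged=np.asarray(g["flagged"], dtype=bool),
                )
            )
    return frames
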
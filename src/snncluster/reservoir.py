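"""3-D small-world LIF reservoir with STDP learning and spike-count logging.

Neurons sit on a 3-D box grid spanning the montage volume; each data channel
injects its spike train into the grid neuron nearest to its electrode.  Pairs
of neurons within a small-world radius are connected in both directions with
random distance-attenuated weights (about 80% excitatory, 20% inhibitory).

During unsupervised training each raster column is streamed as input current,
membrane potentials follow a forward-Euler leaky integrate-and-fire update

    tau_m dv/dt = v_rest - v(t) + R I(t)

and every pre/post spike pair within a nearest-spike window moves the
connecting weight by the exponential STDP kernel

    F(dt) = A+ exp(dt/tau+)   if dt < 0      (pre before post: potentiation)
          = -A- exp(-dt/tau-) if dt >= 0     (post before pre: depression)

with dt = t_pre - t_post.  The spike log A[i, j] counts spikes transmitted
from i to j over the run; it is the raw material of the clustering stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .clustering import ClusterFrame, assign, propagate, symmetrize_affinity
from .data import Montage
from .encoding import SpikeRaster

__all__ = [
    "LIFParams",
    "STDPParams",
    "ReservoirModel",
    "TrainLog",
    "init_reservoir",
    "lif_step",
    "stdp_kernel",
    "train_unsupervised",
    "replay",
]

#: Default neuron grid (x, y, z); ~1200 neurons at desk-scale resolution.
DEFAULT_GRID: tuple[int, int, int] = (10, 12, 10)

#: Default current injected per input spike (in units of the firing threshold
#: times tau_m/dt, i.e. enough to fire an input neuron within one step).
DEFAULT_INPUT_GAIN = 10.0

_EXCITATORY_FRACTION = 0.8
_NEVER = -(10**18)  # sentinel "no spike yet" time


@dataclass
class LIFParams:
    """Leaky integrate-and-fire parameters (time in raster steps).

    ``v_min`` bounds the membrane potential from below (the inhibitory
    reversal potential: hyperpolarisation cannot push the membrane
    arbitrarily far under rest).  The default mirrors the firing threshold
    below rest; ``v_min=None`` disables the bound.
    """

    tau_m: float = 10.0
    v_rest: float = 0.0
    R: float = 1.0
    theta: float = 0.5
    dt: float = 1.0
    refractory: int = 2
    v_min: float | None = -0.5

    def __post_init__(self) -> None:
        if self.tau_m <= 0 or self.dt <= 0:
            raise ValueError("tau_m and dt must be positive")
        if self.theta <= self.v_rest:
            raise ValueError("firing threshold must exceed the resting potential")
        if self.refractory < 0:
            raise ValueError("refractory period must be >= 0")
        if self.v_min is not None and self.v_min > self.v_rest:
            raise ValueError("v_min must not exceed the resting potential")


@dataclass
class STDPParams:
    """Exponential STDP kernel parameters and weight clip bounds."""

    A_plus: float = 0.01
    A_minus: float = 0.012
    tau_plus: float = 10.0
    tau_minus: float = 10.0
    w_min: float = -1.0
    w_max: float = 1.0

    def __post_init__(self) -> None:
        if self.A_plus <= 0 or self.A_minus <= 0:
            raise ValueError("A_plus and A_minus must be positive")
        if self.tau_plus <= 0 or self.tau_minus <= 0:
            raise ValueError("tau_plus and tau_minus must be positive")
        if self.w_min > self.w_max:
            raise ValueError("w_min must not exceed w_max")

    @property
    def pairing_window(self) -> float:
        """Nearest-spike pairing window: 3x the slower kernel time constant."""
        return 3.0 * max(self.tau_plus, self.tau_minus)


@dataclass
class ReservoirModel:
    """Reservoir geometry, weights, input map and runtime state."""

    coords: np.ndarray              # (N, 3)
    w: np.ndarray                   # (N, N) signed weights, w[i, j] = i -> j
    connected: np.ndarray           # (N, N) bool topology mask (fixed)
    input_neurons: np.ndarray       # (v,) neuron index per input channel
    channel_names: list[str]
    spike_log: np.ndarray = field(default=None)   # type: ignore[assignment]
    v_m: np.ndarray = field(default=None)         # type: ignore[assignment]
    refrac: np.ndarray = field(default=None)      # type: ignore[assignment]
    last_spike: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = self.coords.shape[0]
        if self.spike_log is None:
            self.spike_log = np.zeros((n, n), dtype=np.int64)
        if self.v_m is None:
            self.v_m = np.zeros(n)
        if self.refrac is None:
            self.refrac = np.zeros(n, dtype=int)
        if self.last_spike is None:
            self.last_spike = np.full(n, _NEVER, dtype=float)
        if np.any(np.diag(self.w) != 0):
            raise ValueError("self-connections are not allowed")

    @property
    def n_neurons(self) -> int:
        return self.coords.shape[0]

    @property
    def n_inputs(self) -> int:
        return len(self.input_neurons)

    @property
    def Fsrc(self) -> np.ndarray:
        """N x v source matrix: Fsrc[i, j] = 1 iff neuron i inputs channel j."""
        F = np.zeros((self.n_neurons, self.n_inputs))
        F[self.input_neurons, np.arange(self.n_inputs)] = 1.0
        return F

    @property
    def input_coords(self) -> np.ndarray:
        return self.coords[self.input_neurons]

    def reset_state(self, v_rest: float = 0.0) -> None:
        self.v_m[:] = v_rest
        self.refrac[:] = 0
        self.last_spike[:] = _NEVER

    def save(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.attrs["channel_names"] = self.channel_names
            f.create_dataset("coords", data=self.coords)
            f.create_dataset("w", data=self.w)
            f.create_dataset("connected", data=self.connected)
            f.create_dataset("input_neurons", data=self.input_neurons)
            f.create_dataset("spike_log", data=self.spike_log)

    @classmethod
    def load(cls, path: str | Path) -> "ReservoirModel":
        with h5py.File(path, "r") as f:
            return cls(
                coords=np.asarray(f["coords"]),
                w=np.asarray(f["w"]),
                connected=np.asarray(f["connected"], dtype=bool),
                input_neurons=np.asarray(f["input_neurons"], dtype=int),
                channel_names=[str(c) for c in f.attrs["channel_names"]],
                spike_log=np.asarray(f["spike_log"], dtype=np.int64),
            )


def init_reservoir(
    n_grid: tuple[int, int, int] = DEFAULT_GRID,
    montage: Montage | None = None,
    radius: float | None = None,
    seed: int = 0,
    channel_names: list[str] | None = None,
    padding: float = 0.1,
) -> ReservoirModel:
    """Build a grid reservoir around a montage with small-world connectivity.

    Neurons are placed on an ``n_grid`` box grid spanning the montage bounding
    volume (plus fractional ``padding`` per side).  Each channel is assigned
    its nearest grid neuron as input neuron (ties break to the lowest neuron
    index); two channels resolving to the same neuron is an error.  Every
    ordered neuron pair within Euclidean distance ``radius`` is connected with
    weight magnitude uniform on (0, 1) attenuated by (nearest-spacing /
    distance); ~80% of connections are positive.  The default radius is 1.1x
    the largest grid spacing — a local neighbourhood, which keeps spike
    propagation local so each cluster stays dominated by its own centre's
    drive.  Deterministic for a fixed seed.
    """
    if montage is None:
        from .data import default_montage

        montage = default_montage()
    if channel_names is None:
        channel_names = montage.channel_names
    if radius is not None and radius < 0:
        raise ValueError("radius must be >= 0")
    rng = np.random.default_rng(seed)

    elec = montage.coordinates(channel_names)
    lo, hi = elec.min(axis=0), elec.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    lo, hi = lo - padding * span, hi + padding * span
    axes = [np.linspace(lo[d], hi[d], n_grid[d]) for d in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    coords = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    n = coords.shape[0]
    spacing = np.array([(hi[d] - lo[d]) / max(n_grid[d] - 1, 1) for d in range(3)])
    if radius is None:
        radius = 1.1 * float(spacing.max())

    # input mapping: nearest grid neuron per electrode
    d_in = np.linalg.norm(coords[None, :, :] - elec[:, None, :], axis=2)
    input_neurons = np.argmin(d_in, axis=1)
    if len(set(input_neurons.tolist())) != len(channel_names):
        raise ValueError(
            "two channels map to the same grid neuron; use a finer grid"
        )

    dist = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    connected = (dist > 0) & (dist <= radius)
    w = np.zeros((n, n))
    if connected.any():
        d_ref = float(spacing[spacing > 0].min()) if (spacing > 0).any() else 1.0
        mag = rng.uniform(0.0, 1.0, size=(n, n)) * (d_ref / np.where(dist > 0, dist, 1.0))
        sign = np.where(rng.uniform(size=(n, n)) < _EXCITATORY_FRACTION, 1.0, -1.0)
        w = np.where(connected, mag * sign, 0.0)
    return ReservoirModel(
        coords=coords,
        w=w,
        connected=connected,
        input_neurons=input_neurons.astype(int),
        channel_names=list(channel_names),
    )


def lif_step(
    model: ReservoirModel, input_current: np.ndarray, params: LIFParams
) -> np.ndarray:
    """Advance membrane potentials one Euler step; return the fired mask.

    Non-refractory neurons integrate v += (dt/tau_m)(v_rest - v + R*I) and
    fire when v >= theta, then reset to v_rest and enter the refractory
    period (during which they do not integrate).  The pre-reset potentials
    are left in ``model.v_last`` for recording.
    """
    I = np.asarray(input_current, dtype=float)
    if not np.all(np.isfinite(I)):
        raise ValueError("input current must be finite")
    active = model.refrac <= 0
    v = model.v_m
    v[active] += (params.dt / params.tau_m) * (
        params.v_rest - v[active] + params.R * I[active]
    )
    if params.v_min is not None:
        np.maximum(v, params.v_min, out=v)
    v[~active] = params.v_rest
    model.v_last = v.copy()
    fired = active & (v >= params.theta)
    v[fired] = params.v_rest
    model.refrac[~active] -= 1
    model.refrac[fired] = params.refractory
    return fired


def stdp_kernel(delta_t: float | np.ndarray, params: STDPParams) -> float | np.ndarray:
    """STDP weight change for spike-time difference dt = t_pre - t_post."""
    dt = np.asarray(delta_t, dtype=float)
    out = np.where(
        dt < 0,
        params.A_plus * np.exp(dt / params.tau_plus),
        -params.A_minus * np.exp(-dt / params.tau_minus),
    )
    return float(out) if np.isscalar(delta_t) or out.ndim == 0 else out


@dataclass
class TrainLog:
    """Bookkeeping from an unsupervised training run."""

    frames: list[ClusterFrame]
    streamed_points: int
    sample_bounds: list[tuple[int, int]]  # [start, end) global step per sample
    v_hist: np.ndarray | None = None      # (T_total, N) pre-reset potentials
    fire_hist: np.ndarray | None = None   # (T_total, N) bool


def _snapshot(
    model: ReservoirModel,
    t: int,
    alpha: float,
    normalization: str,
    F_prev: np.ndarray | None,
    tol: float,
) -> ClusterFrame:
    from scipy import sparse

    # sparse path: the spike graph only has entries on the (local) connections
    A_prime = symmetrize_affinity(sparse.csr_matrix(model.spike_log))
    F_star = propagate(
        A_prime, model.Fsrc, alpha=alpha, mode="iterative",
        tol=tol, normalization=normalization, F0=F_prev,
    )
    labels, sizes, flagged = assign(F_star, model.coords, model.input_neurons)
    return ClusterFrame(t=t, F_star=F_star, labels=labels, sizes=sizes, flagged=flagged)


def _clip_touched(w: np.ndarray, connected: np.ndarray, fired: np.ndarray, p: STDPParams) -> None:
    # clip only rows/cols touched this step; keep non-connections at exactly 0
    sub = w[:, fired]
    np.clip(sub, p.w_min, p.w_max, out=sub)
    sub[~connected[:, fired]] = 0.0
    w[:, fired] = sub
    sub = w[fired, :]
    np.clip(sub, p.w_min, p.w_max, out=sub)
    sub[~connected[fired, :]] = 0.0
    w[fired, :] = sub


def train_unsupervised(
    model: ReservoirModel,
    rasters: list[SpikeRaster],
    lif: LIFParams | None = None,
    stdp: STDPParams | None = None,
    snapshot_every: int = 5,
    clustering_alpha: float = 0.9,
    normalization: str = "sqrt",
    propagate_tol: float = 1e-8,
    input_gain: float = DEFAULT_INPUT_GAIN,
    record: bool = False,
) -> TrainLog:
    """Stream rasters through the reservoir with STDP; snapshot clustering.

    Each raster column injects ``input_gain`` current (signed by the spike
    polarity) into the corresponding input neurons; spikes then propagate
    through the weighted connections (a spike of neuron i at step t delivers
    current w[i, j] to neuron j at step t+1).  STDP pairs each spike with its
    partners' nearest previous spikes inside the pairing window; weights are
    clipped to [w_min, w_max].  ``spike_log[i, j]`` increments whenever i
    spikes over a live connection i -> j.  A clustering frame (including an
    initial F* = Fsrc frame at t=0) is recorded every ``snapshot_every``
    streamed points and at the end of the stream.

    With ``record=True`` the per-step pre-reset membrane potentials and fired
    masks are kept for trace analytics.
    """
    lif = lif or LIFParams()
    stdp = stdp or STDPParams()
    for r in rasters:
        if r.n_channels != model.n_inputs:
            raise ValueError(
                f"raster has {r.n_channels} channels; reservoir expects {model.n_inputs}"
            )
    model.reset_state(lif.v_rest)
    n = model.n_neurons
    window = stdp.pairing_window
    frames = [
        _snapshot(model, 0, clustering_alpha, normalization, None, propagate_tol)
    ]
    v_hist: list[np.ndarray] = []
    fire_hist: list[np.ndarray] = []
    sample_bounds: list[tuple[int, int]] = []
    t = 0
    prev_fired = np.zeros(n, dtype=bool)
    for raster in rasters:
        start = t
        for col in raster.events.T:
            I = np.zeros(n)
            nz = col != 0
            if nz.any():
                I[model.input_neurons[nz]] += input_gain * col[nz]
            if prev_fired.any():
                I += model.w[prev_fired].sum(axis=0)
            fired = lif_step(model, I, lif)
            if record:
                v_hist.append(model.v_last)
                fire_hist.append(fired.copy())
            if fired.any():
                recent = (t - model.last_spike) <= window
                # pre spiked earlier, post fires now -> potentiation on w[:, fired]
                pot = np.where(
                    recent, stdp.A_plus * np.exp((model.last_spike - t) / stdp.tau_plus), 0.0
                )
                model.w[:, fired] += pot[:, None] * model.connected[:, fired]
                # post spiked earlier, pre fires now -> depression on w[fired, :]
                dep = np.where(
                    recent, stdp.A_minus * np.exp(-(t - model.last_spike) / stdp.tau_minus), 0.0
                )
                model.w[fired, :] -= dep[None, :] * model.connected[fired, :]
                _clip_touched(model.w, model.connected, fired, stdp)
                model.spike_log[fired, :] += model.connected[fired, :]
                model.last_spike[fired] = t
            prev_fired = fired
            t += 1
            if t % snapshot_every == 0:
                frames.append(
                    _snapshot(
                        model, t, clustering_alpha, normalization,
                        frames[-1].F_star, propagate_tol,
                    )
                )
        sample_bounds.append((start, t))
    if frames[-1].t != t:
        frames.append(
            _snapshot(model, t, clustering_alpha, normalization, frames[-1].F_star, propagate_tol)
        )
    return TrainLog(
        frames=frames,
        streamed_points=t,
        sample_bounds=sample_bounds,
        v_hist=np.array(v_hist) if record else None,
        fire_hist=np.array(fire_hist, dtype=bool) if record else None,
    )


def replay(
    model: ReservoirModel,
    raster: SpikeRaster,
    lif: LIFParams | None = None,
    input_gain: float = DEFAULT_INPUT_GAIN,
) -> np.ndarray:
    """Run one raster through the frozen reservoir (no STDP, no logging).

    Returns the (T, N) boolean fired history.  The model's weights and spike
    log are untouched; its transient state is reset before and after.
    """
    lif = lif or LIFParams()
    if raster.n_channels != model.n_inputs:
        raise ValueError("raster channel count does not match the reservoir")
    model.reset_state(lif.v_rest)
    n = model.n_neurons
    fired_hist = np.zeros((raster.n_times, n), dtype=bool)
    prev_fired = np.zeros(n, dtype=bool)
    for ti, col in enumerate(raster.events.T):
        I = np.zeros(n)
        nz = col != 0
        if nz.any():
            I[model.input_neurons[nz]] += input_gain * col[nz]
        if prev_fired.any():
            I += model.w[prev_fired].sum(axis=0)
        fired = lif_step(model, I, lif)
        fired_hist[ti] = fired
        prev_fired = fired
    model.reset_state(lif.v_rest)
    return fired_hist
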
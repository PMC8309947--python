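"""End-to-end pipeline: configuration, staged execution and artifacts.

``run`` executes encode -> reservoir init -> unsupervised STDP training (with
clustering frames) -> cluster traces and PSP summaries -> feature selection ->
silhouette validity -> per-class rule extraction -> leave-one-out deSNN
classification, writing every artifact plus a manifest (config hash and seed)
into a run directory.  Expensive stages persist their state (reservoir
checkpoint, frame log, potential recordings) so later stages can resume from
disk: ``run(config, stages=["cluster", ...])`` reloads the checkpoint instead
of retraining.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import yaml

from . import analytics, clustering, desnn, rules, validity
from .data import (
    DEFAULT_PLANTED,
    Montage,
    SampleSet,
    default_montage,
    generate_dataset,
    read_samples,
    synthetic_montage,
)
from .encoding import encode_samples
from .reservoir import (
    DEFAULT_GRID,
    LIFParams,
    ReservoirModel,
    STDPParams,
    TrainLog,
    init_reservoir,
    train_unsupervised,
)

__all__ = ["PipelineConfig", "run", "STAGES"]

STAGES = ("data", "encode", "train", "cluster", "select", "validity", "rules", "classify")


@dataclass
class SyntheticConfig:
    n_per_class: int = 20
    v: int = 26
    length: int = 75
    planted: tuple[int, ...] = DEFAULT_PLANTED
    effect: float = 2.0


@dataclass
class ReservoirConfig:
    grid: tuple[int, int, int] = DEFAULT_GRID
    radius: float | None = None
    input_gain: float = 10.0
    lif: LIFParams = field(default_factory=LIFParams)
    stdp: STDPParams = field(default_factory=STDPParams)


@dataclass
class ClusteringConfig:
    alpha: float = 0.9
    normalization: str = "sqrt"
    snapshot_every: int = 5
    adjacency_factor: float = 2.0


@dataclass
class AnalyticsConfig:
    statistic: str = "area"
    k_top: int = 8
    mutual: bool = False
    area_rule: str = "rectangle"


@dataclass
class RulesConfig:
    ell: float | str = "auto"  # "auto" = per-cluster mean + 1 SD
    window_L: int = 3
    inclusive_tail: bool = True


@dataclass
class DesnnConfig:
    mod: float = 0.995
    drift: float = 0.005
    shared_reservoir: bool = False


@dataclass
class ValidityConfig:
    use_abs_weights: bool = True


@dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: str = "snncluster_run"
    data_path: str | None = None  # None -> synthetic data
    data_format: str = "csv-dir"
    encoding_threshold: float | str = "auto"
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    reservoir: ReservoirConfig = field(default_factory=ReservoirConfig)
    clustering: ClusteringConfig = field(default_factory=ClusteringConfig)
    analytics: AnalyticsConfig = field(default_factory=AnalyticsConfig)
    rules: RulesConfig = field(default_factory=RulesConfig)
    desnn: DesnnConfig = field(default_factory=DesnnConfig)
    validity: ValidityConfig = field(default_factory=ValidityConfig)

    def to_dict(self) -> dict:
        def clean(obj):
            if dataclasses.is_dataclass(obj):
                return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (tuple, list)):
                return [clean(x) for x in obj]
            return obj

        return clean(self)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (the output location does not
        change what is computed, so it is excluded)."""
        d = self.to_dict()
        d.pop("output_dir", None)
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sub = {
            "synthetic": SyntheticConfig,
            "clustering": ClusteringConfig,
            "analytics": AnalyticsConfig,
            "rules": RulesConfig,
            "desnn": DesnnConfig,
            "validity": ValidityConfig,
        }
        kwargs: dict = {}
        for key, typ in sub.items():
            if key in d:
                sd = dict(d.pop(key))
                if key == "synthetic" and "planted" in sd:
                    sd["planted"] = tuple(sd["planted"])
                kwargs[key] = typ(**sd)
        if "reservoir" in d:
            rd = dict(d.pop("reservoir"))
            if "grid" in rd:
                rd["grid"] = tuple(rd["grid"])
            if "lif" in rd:
                rd["lif"] = LIFParams(**rd["lif"])
            if "stdp" in rd:
                rd["stdp"] = STDPParams(**rd["stdp"])
            kwargs["reservoir"] = ReservoirConfig(**rd)
        kwargs.update(d)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f) or {})


class StageError(RuntimeError):
    """A pipeline stage failed; earlier artifacts are retained."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _montage_for(sample_set: SampleSet) -> Montage:
    base = default_montage()
    if all(n in base.entries for n in sample_set.channel_names):
        return base
    return synthetic_montage(sample_set.channel_names)


def _save_record(log: TrainLog, path: Path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["streamed_points"] = log.streamed_points
        f.create_dataset("v_hist", data=log.v_hist.astype(np.float32))
        f.create_dataset("fire_hist", data=log.fire_hist.astype(np.uint8))
        f.create_dataset("sample_bounds", data=np.array(log.sample_bounds))


def _load_record(path: Path, frames) -> TrainLog:
    with h5py.File(path, "r") as f:
        return TrainLog(
            frames=frames,
            streamed_points=int(f.attrs["streamed_points"]),
            sample_bounds=[tuple(b) for b in np.asarray(f["sample_bounds"])],
            v_hist=np.asarray(f["v_hist"], dtype=float),
            fire_hist=np.asarray(f["fire_hist"], dtype=bool),
        )


def run(config: PipelineConfig, stages: list[str] | None = None) -> Path:
    """Execute the pipeline (or a subset of stages) into the run directory.

    Stages not requested are either recomputed cheaply (data, encode) or
    resumed from the artifacts of a previous run (train).  Returns the run
    directory path.  Any stage failure raises :class:`StageError`; artifacts
    written before the failure are retained.
    """
    wanted = list(STAGES) if stages is None else list(stages)
    unknown = [s for s in wanted if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stages {unknown}; valid: {STAGES}")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- data (always needed in memory; deterministic from config) ---------
    try:
        if config.data_path is not None:
            samples = read_samples(config.data_path, config.data_format)
        else:
            sc = config.synthetic
            samples = generate_dataset(
                sc.n_per_class, sc.v, sc.length, sc.planted, sc.effect, config.seed
            )
        # seeded shuffle of the streaming order: unsupervised weight drift over
        # the stream must not be confounded with class (labels stay exchangeable
        # with respect to stream position)
        order = np.random.default_rng(config.seed).permutation(samples.n_samples)
        samples = SampleSet(
            [samples.samples[i] for i in order],
            samples.labels[order],
            samples.channel_names,
            samples.sampling_note,
        )
        montage = _montage_for(samples)
    except Exception as e:  # noqa: BLE001
        raise StageError("data", e) from e

    # --- encode -------------------------------------------------------------
    try:
        rasters = encode_samples(samples, config.encoding_threshold)
    except Exception as e:  # noqa: BLE001
        raise StageError("encode", e) from e

    # --- train (expensive; persisted and resumable) --------------------------
    rc = config.reservoir
    if "train" in wanted:
        try:
            model = init_reservoir(
                rc.grid, montage, rc.radius, config.seed, samples.channel_names
            )
            log = train_unsupervised(
                model, rasters, lif=rc.lif, stdp=rc.stdp,
                snapshot_every=config.clustering.snapshot_every,
                clustering_alpha=config.clustering.alpha,
                normalization=config.clustering.normalization,
                input_gain=rc.input_gain, record=True,
            )
            model.save(out / "checkpoint.h5")
            clustering.write_frame_log(log.frames, out / "frames.h5")
            _save_record(log, out / "record.h5")
        except StageError:
            raise
        except Exception as e:  # noqa: BLE001
            raise StageError("train", e) from e
    else:
        try:
            model = ReservoirModel.load(out / "checkpoint.h5")
            frames = clustering.read_frame_log(out / "frames.h5")
            log = _load_record(out / "record.h5", frames)
        except Exception as e:  # noqa: BLE001
            raise StageError("train", e) from e

    adjacency = clustering.cluster_adjacency(
        model.input_coords, config.clustering.adjacency_factor
    )
    final = log.frames[-1]

    # --- cluster: final clustering summary + fuzzy boundaries ---------------
    if "cluster" in wanted:
        try:
            boundaries = clustering.fuzzy_boundaries(log.frames, adjacency)
            clustering.boundary_report(boundaries, out / "boundaries.csv")
        except Exception as e:  # noqa: BLE001
            raise StageError("cluster", e) from e

    # --- select: traces, summaries, feature ranking -------------------------
    traces = summaries = None
    if "select" in wanted or "rules" in wanted:
        try:
            traces = analytics.compute_traces(model, log, rasters)
            summaries = analytics.psp_summaries(
                traces, log.sample_bounds, samples.labels, config.analytics.area_rule
            )
        except Exception as e:  # noqa: BLE001
            raise StageError("select", e) from e
    if "select" in wanted:
        try:
            summaries.to_csv(out / "summaries.csv", index=False)
            ranking, top = analytics.select_features(
                summaries, config.analytics.statistic,
                config.analytics.k_top, config.analytics.mutual,
            )
            ranking = ranking.copy()
            ranking["channel_name"] = [
                samples.channel_names[c] for c in ranking["channel"]
            ]
            ranking.to_csv(out / "ranking.csv", index=False)
            (out / "top_channels.json").write_text(
                json.dumps(
                    {"top": top, "names": [samples.channel_names[c] for c in top]}
                )
            )
        except Exception as e:  # noqa: BLE001
            raise StageError("select", e) from e

    # --- validity ------------------------------------------------------------
    if "validity" in wanted:
        try:
            report = validity.silhouette(
                model, final.labels, final.F_star, adjacency,
                config.validity.use_abs_weights,
            )
            report.to_csv(out / "silhouette.csv")
        except Exception as e:  # noqa: BLE001
            raise StageError("validity", e) from e

    # --- rules: per-class mean PSP traces -> actions -> rendered rules ------
    if "rules" in wanted:
        try:
            rendered, exported = [], []
            for cls in samples.classes:
                idx = np.nonzero(samples.labels == cls)[0]
                seg_len = min(log.sample_bounds[i][1] - log.sample_bounds[i][0] for i in idx)
                actions = []
                for tr in traces:
                    mean_psp = np.mean(
                        [tr.mu_psp[log.sample_bounds[i][0]:(log.sample_bounds[i][0] + seg_len)]
                         for i in idx],
                        axis=0,
                    )
                    ell = (
                        rules.default_event_threshold(mean_psp)
                        if config.rules.ell == "auto"
                        else float(config.rules.ell)
                    )
                    events = rules.extract_events(mean_psp, ell, tr.cluster_id)
                    actions.extend(
                        rules.detect_actions(
                            events, config.rules.window_L, config.rules.inclusive_tail
                        )
                    )
                rule = rules.assemble_rules(actions, int(cls), config.rules.window_L)
                rendered.append(rules.render_rule(rule, samples.channel_names))
                exported.append(json.loads(rules.rule_to_json(rule)))
            (out / "rules.txt").write_text("\n".join(rendered) + "\n")
            (out / "rules.json").write_text(json.dumps(exported, indent=1))
        except Exception as e:  # noqa: BLE001
            raise StageError("rules", e) from e

    # --- classify: leave-one-out deSNN ---------------------------------------
    if "classify" in wanted:
        try:
            result = desnn.loocv(
                samples, grid=rc.grid, radius=rc.radius, seed=config.seed,
                lif=rc.lif, stdp=rc.stdp,
                desnn_params=desnn.DeSNNParams(config.desnn.mod, config.desnn.drift),
                encode_threshold=config.encoding_threshold,
                input_gain=rc.input_gain,
                shared_reservoir=config.desnn.shared_reservoir,
                montage=montage,
            )
            (out / "cv_report.json").write_text(json.dumps(result.to_dict(), indent=1))
        except Exception as e:  # noqa: BLE001
            raise StageError("classify", e) from e

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "streamed_points": log.streamed_points,
        "stages_run": wanted,
        "artifacts": sorted(p.name for p in out.iterdir() if p.name != "manifest.json"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out
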
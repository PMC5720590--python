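"""Config-driven end-to-end orchestration.

Stages: generate (or read) trajectories for both variants → pool all
frames in one deterministic order (variant, replicate, frame) → cluster
the pooled frames in a shared state space (k-centers at the cutoff, then
k-medoids refinement) → per-variant transition counting and transpose
MSM → top-occupancy microstate selection → crystal-normalized probe
distances and the between-variant comparison, plus a cluster-population
overlap summary.

One global seed is expanded through ``numpy.random.SeedSequence`` into
independent per-stage substreams, so e.g. changing the generator noise
does not perturb clustering tie-breaks.  Identical config + seed gives
byte-identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .allostery import (
    OverlapSummary,
    TTestResult,
    compare_variants,
    microstate_representative,
    normalize_distance,
    occupancy_overlap,
    probe_displacement,
    probe_distance,
)
from .cluster import ClusterModel, FrameRef, RmsdMetric, kcenters, kmedoids_refine
from .msm import MSModel, build_msm, count_transitions, raw_occupancy, top_occupied
from .structure import (
    AtomSelection,
    ProbePair,
    ReferenceStructure,
    Trajectory,
    read_multimodel_pdb,
    read_reference_pdb,
    resolve_selection,
)
from .synthetic import GeneratorConfig, aggregate_time_ps, make_variant_pair

logger = logging.getLogger(__name__)

__all__ = ["ConfigError", "RunConfig", "validate_config", "run_analysis",
            "run_pipeline", "PipelineResult"]


class ConfigError(ValueError):
    pass


#: Generator keys accepted in the YAML ``generator:`` section, forwarded to
#: :meth:`GeneratorConfig.default`.
_GENERATOR_KEYS = {
    "n_replicates", "frames_per_replicate", "noise_sigma", "mode_sigma",
    "n_modes", "rigid_max_rotation_deg", "rigid_max_translation",
    "frame_interval", "stationary_wildtype", "stationary_mutant",
    "metastability", "planted_norm_wildtype", "planted_norm_mutant",
    "state_separation",
}


@dataclass
class RunConfig:
    """Normalized run configuration; defaults mirror the reference protocol
    (1 Å cutoff, 50 refinement iterations, lag 1 frame = 10 ps, top 5%)."""

    mode: str = "synthetic"  # "synthetic" | "files"
    generator: dict[str, Any] = field(default_factory=dict)
    files: dict[str, Any] = field(default_factory=dict)
    state_space: list[AtomSelection] = field(default_factory=lambda: [
        AtomSelection("A", 425, 429, "backbone"),
        AtomSelection("B", 445, 477, "backbone"),
    ])
    anchor: AtomSelection = field(
        default_factory=lambda: AtomSelection("B", 445, 459, "backbone")
    )
    probe: ProbePair = field(default_factory=lambda: ProbePair("A", 427, "B", 477))
    cutoff: float = 1.0  # Å
    n_iterations: int = 50
    lag: int = 1  # stored frames
    fraction: float = 0.05
    occupancy_source: str = "msm"  # "msm" | "raw"
    distance_mode: str = "medoid"  # "medoid" | "frames"
    welch: bool = False
    overlap_floor: float = 0.0
    medoid_max_exact: int = 4000
    seed: int = 0
    outdir: str | None = None

    def validate(self) -> "RunConfig":
        if self.mode not in ("synthetic", "files"):
            raise ConfigError(f"mode must be 'synthetic' or 'files', got {self.mode!r}")
        if self.cutoff <= 0:
            raise ConfigError(f"cutoff must be positive, got {self.cutoff}")
        if self.n_iterations < 0:
            raise ConfigError("n_iterations must be >= 0")
        if self.lag < 1:
            raise ConfigError("lag must be >= 1 frame")
        if not (0.0 < self.fraction <= 1.0):
            raise ConfigError(f"fraction must be in (0, 1], got {self.fraction}")
        if self.occupancy_source not in ("msm", "raw"):
            raise ConfigError("occupancy_source must be 'msm' or 'raw'")
        if self.distance_mode not in ("medoid", "frames"):
            raise ConfigError("distance_mode must be 'medoid' or 'frames'")
        unknown = set(self.generator) - _GENERATOR_KEYS
        if unknown:
            raise ConfigError(f"unknown generator keys: {sorted(unknown)}")
        if self.mode == "files":
            if "variants" not in self.files or "reference" not in self.files:
                raise ConfigError(
                    "files mode needs files.variants (variant -> [paths]) "
                    "and files.reference"
                )
            for variant, paths in self.files["variants"].items():
                for p in paths:
                    if not Path(p).exists():
                        raise ConfigError(f"missing trajectory for {variant}: {p}")
            if not Path(self.files["reference"]).exists():
                raise ConfigError(f"missing reference: {self.files['reference']}")
        return self


def _selection_from_dict(d: dict) -> AtomSelection:
    atoms = d.get("atoms", "backbone")
    if isinstance(atoms, list):
        atoms = tuple(atoms)
    return AtomSelection(d["chain"], int(d["res_first"]), int(d["res_last"]), atoms)


_TOP_KEYS = {
    "mode", "generator", "files", "state_space", "anchor", "probe", "cutoff",
    "n_iterations", "lag", "fraction", "occupancy_source", "distance_mode",
    "welch", "overlap_floor", "medoid_max_exact", "seed", "outdir",
}


def validate_config(path: str | Path) -> RunConfig:
    """Load, schema-check and normalize a YAML run config.

    Unknown keys are errors, not warnings; an empty file yields the fully
    defaulted synthetic configuration.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a YAML mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    kwargs: dict[str, Any] = dict(raw)
    try:
        if "state_space" in kwargs:
            kwargs["state_space"] = [
                _selection_from_dict(d) for d in kwargs["state_space"]
            ]
        if "anchor" in kwargs:
            kwargs["anchor"] = _selection_from_dict(kwargs["anchor"])
        if "probe" in kwargs:
            p = kwargs["probe"]
            kwargs["probe"] = ProbePair(
                p["chain_a"], int(p["res_a"]), p["chain_b"], int(p["res_b"])
            )
        config = RunConfig(**kwargs)
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"malformed config: {exc}") from exc
    return config.validate()


@dataclass
class VariantResult:
    msm: MSModel
    occupancy: np.ndarray  # ranking source (pi or raw counts)
    selected: np.ndarray  # selected microstate indices
    table: pd.DataFrame  # per-selected-microstate distance rows


@dataclass
class PipelineResult:
    config: RunConfig
    reference: ReferenceStructure
    cluster_model: ClusterModel
    frame_refs: list[FrameRef]
    variants: dict[str, VariantResult]
    ttest: TTestResult
    overlap: OverlapSummary
    aggregate_time_ps: float | None = None
    kcenters_radius: float | None = None  # coverage radius before refinement

    @property
    def distance_table(self) -> pd.DataFrame:
        return pd.concat(
            [v.table for v in self.variants.values()], ignore_index=True
        )


def _stage_seeds(seed: int, n: int) -> list[int]:
    """Independent per-stage integer seeds derived from the global seed."""
    return [int(s.generate_state(1)[0] % (2**31)) for s in
            np.random.SeedSequence(seed).spawn(n)]


def _load_files(config: RunConfig) -> tuple[dict[str, list[Trajectory]], ReferenceStructure]:
    trajectories: dict[str, list[Trajectory]] = {}
    for variant, paths in config.files["variants"].items():
        trajectories[variant] = [
            read_multimodel_pdb(p, variant=variant, replicate=r)
            for r, p in enumerate(paths)
        ]
    reference = read_reference_pdb(config.files["reference"], config.probe)
    return trajectories, reference


def run_analysis(config: RunConfig) -> PipelineResult:
    """Execute the full analysis in memory and return the result bundle."""
    config.validate()
    gen_seed, cluster_seed = _stage_seeds(config.seed, 2)

    # --- stage 1: data -----------------------------------------------------
    agg_ps = None
    if config.mode == "synthetic":
        gen = GeneratorConfig.default(seed=gen_seed, **config.generator)
        trajectories, reference, _truth = make_variant_pair(gen)
        agg_ps = aggregate_time_ps(gen)
    else:
        trajectories, reference = _load_files(config)
    logger.info("loaded %d variants", len(trajectories))

    # --- stage 2: pooled frame collection ---------------------------------
    variants = sorted(trajectories)
    refs: list[FrameRef] = []
    stacks: list[np.ndarray] = []
    seq_slices: dict[str, list[slice]] = {v: [] for v in variants}
    offset = 0
    topology = None
    for variant in variants:
        for traj in sorted(trajectories[variant], key=lambda t: t.replicate or 0):
            if topology is None:
                topology = traj.topology
            elif traj.topology != topology:
                raise ValueError(
                    f"stage pooling: topology of {variant} replicate "
                    f"{traj.replicate} differs from the first trajectory"
                )
            stacks.append(traj.coords)
            refs.extend(
                FrameRef(variant, traj.replicate or 0, f)
                for f in range(traj.n_frames)
            )
            seq_slices[variant].append(slice(offset, offset + traj.n_frames))
            offset += traj.n_frames
    pool = np.concatenate(stacks, axis=0)
    selection = resolve_selection(topology, config.state_space)
    metric = RmsdMetric(selection_indices=selection)

    # --- stage 3: shared-state-space clustering ----------------------------
    model = kcenters(pool, config.cutoff, metric, frame_refs=refs)
    kcenters_radius = model.radius
    logger.info("k-centers: %d clusters, radius %.3f Å", model.n_clusters, model.radius)
    model = kmedoids_refine(pool, model, config.n_iterations, seed=cluster_seed,
                            max_exact=config.medoid_max_exact, frame_refs=refs)
    logger.info("k-medoids: %d clusters, objective %.2f", model.n_clusters,
                model.objective)

    # --- stage 4/5: per-variant MSM, selection, distances ------------------
    per_variant: dict[str, VariantResult] = {}
    samples: dict[str, np.ndarray] = {}
    for variant in variants:
        seqs = [model.assignments[s] for s in seq_slices[variant]]
        counts = count_transitions(seqs, model.n_clusters, lag=config.lag,
                                   variant=variant)
        msm = build_msm(counts)
        occupancy = (msm.stationary if config.occupancy_source == "msm"
                     else raw_occupancy(seqs, model.n_clusters))
        selected = top_occupied(occupancy, config.fraction)
        rows = []
        for state in selected:
            rep = microstate_representative(model, int(state))
            pool_idx = int(model.medoid_pool_indices[int(state)])
            coords = pool[pool_idx]
            d = probe_distance(coords, topology, config.probe)
            rows.append({
                "variant": variant,
                "microstate": int(state),
                "occupancy": float(occupancy[state]),
                "medoid_variant": rep.variant,
                "medoid_replicate": rep.replicate,
                "medoid_frame": rep.frame_index,
                "distance_A": d,
                "normalized_distance": normalize_distance(d, reference),
                "probe_displacement_A": probe_displacement(
                    coords, topology, reference, config.anchor),
            })
        table = pd.DataFrame(rows)
        if config.distance_mode == "medoid":
            samples[variant] = table["normalized_distance"].to_numpy()
        else:
            own = np.concatenate(
                [np.flatnonzero(np.isin(model.assignments[s], selected)) + s.start
                 for s in seq_slices[variant]]
            )
            ia, ib = config.probe.indices(topology)
            dists = np.linalg.norm(pool[own, ia, :] - pool[own, ib, :], axis=1)
            samples[variant] = dists / reference.d_ref
        per_variant[variant] = VariantResult(
            msm=msm, occupancy=occupancy, selected=selected, table=table
        )

    # --- stage 6: comparison ----------------------------------------------
    wt, mut = "wildtype", "mutant"
    if wt not in per_variant or mut not in per_variant:
        # generic two-variant fallback: compare in sorted order
        wt, mut = variants[:2]
    ttest = compare_variants(samples[wt], samples[mut], welch=config.welch)
    overlap = occupancy_overlap(
        per_variant[wt].occupancy, per_variant[mut].occupancy,
        floor=config.overlap_floor,
    )
    return PipelineResult(
        config=config,
        reference=reference,
        cluster_model=model,
        frame_refs=refs,
        variants=per_variant,
        ttest=ttest,
        overlap=overlap,
        aggregate_time_ps=agg_ps,
        kcenters_radius=kcenters_radius,
    )


def _config_manifest(config: RunConfig) -> dict:
    d = asdict(config)
    d["state_space"] = [asdict(s) for s in config.state_space]
    d["anchor"] = asdict(config.anchor)
    d["probe"] = asdict(config.probe)
    return d


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the analysis and write all reports to ``config.outdir``."""
    if config.outdir is None:
        raise ConfigError("run_pipeline needs an output directory")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result = run_analysis(config)
    model = result.cluster_model

    # cluster model + assignments
    cluster_meta = {
        "n_clusters": model.n_clusters,
        "cutoff_A": model.cutoff,
        "radius_A": model.radius,
        "n_iterations": model.n_iterations,
        "objective_history": model.objective_history,
        "metric": model.metric.describe(),
        "medoids": [asdict(r) for r in model.medoid_refs],
    }
    (outdir / "cluster_model.json").write_text(json.dumps(cluster_meta, indent=1))
    pd.DataFrame({
        "variant": [r.variant for r in result.frame_refs],
        "replicate": [r.replicate for r in result.frame_refs],
        "frame_index": [r.frame_index for r in result.frame_refs],
        "cluster": model.assignments,
        "distance_to_medoid_A": model.distances,
    }).to_csv(outdir / "assignments.tsv", sep="\t", index=False)

    for variant, vres in result.variants.items():
        k = model.n_clusters
        idx = [str(i) for i in range(k)]
        pd.DataFrame(vres.msm.counts.counts, columns=idx).to_csv(
            outdir / f"counts_{variant}.tsv", sep="\t", index=False)
        pd.DataFrame(vres.msm.transition, columns=idx).to_csv(
            outdir / f"transition_{variant}.tsv", sep="\t", index=False)
        pd.DataFrame({"cluster": range(k),
                      "stationary": vres.msm.stationary,
                      "occupancy_used": vres.occupancy}).to_csv(
            outdir / f"occupancy_{variant}.tsv", sep="\t", index=False)
        (outdir / f"selection_{variant}.json").write_text(json.dumps({
            "fraction": result.config.fraction,
            "occupancy_source": result.config.occupancy_source,
            "selected": [int(s) for s in vres.selected],
            "lag_frames": result.config.lag,
        }, indent=1))

    result.distance_table.to_csv(outdir / "distance_report.tsv", sep="\t",
                                 index=False)
    (outdir / "distance_report.json").write_text(json.dumps({
        "t": result.ttest.t, "df": result.ttest.df, "p": result.ttest.p,
        "mean_wildtype": result.ttest.mean_a, "sd_wildtype": result.ttest.sd_a,
        "mean_mutant": result.ttest.mean_b, "sd_mutant": result.ttest.sd_b,
        "n_wildtype": result.ttest.n_a, "n_mutant": result.ttest.n_b,
        "degenerate_variance": result.ttest.degenerate_variance,
        "d_ref_A": result.reference.d_ref,
        "distance_mode": result.config.distance_mode,
    }, indent=1))
    (outdir / "overlap_summary.json").write_text(json.dumps({
        "n_exclusive_wildtype": result.overlap.n_exclusive_a,
        "n_exclusive_mutant": result.overlap.n_exclusive_b,
        "n_shared": result.overlap.n_shared,
        "jensen_shannon_nats": result.overlap.jensen_shannon_nats,
    }, indent=1))

    manifest = {
        "software": {"name": "allomsm", "version": __version__},
        "config": _config_manifest(result.config),
        "seed": result.config.seed,
        "aggregate_time_ps_per_variant": result.aggregate_time_ps,
        "n_pooled_frames": len(result.frame_refs),
        "n_clusters": model.n_clusters,
    }
    if config.mode == "files":
        manifest["input_hashes"] = {
            str(p): hashlib.sha256(Path(p).read_bytes()).hexdigest()
            for paths in config.files["variants"].values() for p in paths
        }
        manifest["input_hashes"][str(config.files["reference"])] = hashlib.sha256(
            Path(config.files["reference"]).read_bytes()).hexdigest()
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return result
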
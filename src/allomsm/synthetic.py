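"""Synthetic conformational-ensemble generator with planted ground truth.

Real MD trajectories of the nuclear-receptor heterodimer are not
available, so this module emulates them: a small two-chain backbone
topology (chain A, RXRA-like, residues 400–460; chain B, PPARG-like,
residues 440–480; four backbone-heavy atoms per residue), a handful of
planted metastable states visited according to a per-variant Markov
chain, per-state reference geometries, and per-frame noise.

Each frame is its state geometry plus three kinds of perturbation:

* low-dimensional collective "breathing" modes on the AF2-region atoms
  with Gaussian amplitudes (``n_modes``, ``mode_sigma``) — the
  correlated backbone fluctuation that gives real ensembles their
  continuous conformational diversity.  Purely isotropic noise cannot
  play this role: over ~150 selected atoms all pairwise distances
  concentrate tightly around sigma*sqrt(6), so a covering-radius
  clusterer sees either one blob per state or one cluster per frame;
* small isotropic Gaussian coordinate noise (``noise_sigma``);
* a random proper rigid-body transform (rotation up to a maximum angle,
  translation up to a maximum norm) exercising the superposition stage.

The two variants share state geometries except in the probe region: the
terminal-tyrosine residue of chain B is placed, per state and variant,
at an exact planted distance from the chain-A probe Cα along their
connecting line, so planted probe distances are exact by construction.
The mutant's planted chain shifts occupancy toward states whose probe
pair sits nearer the reference (agonist-crystal stand-in) distance,
emulating the allosteric pull of the mutated interface residue on the
AF2 tyrosine.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .structure import (
    BACKBONE_HEAVY,
    ProbePair,
    ReferenceStructure,
    StructureError,
    Topology,
    Trajectory,
    write_multimodel_pdb,
    write_reference_pdb,
)

__all__ = ["VARIANTS", "GeneratorConfig", "PlantedTruth", "make_default_topology",
           "base_geometry", "sample_state_path", "emit_trajectory",
           "make_variant_pair", "analytic_stationary", "aggregate_time_ps",
           "write_dataset"]

#: Variant labels, also the lexicographic pooling order used downstream.
VARIANTS = ("wildtype", "mutant")

# Backbone atom offsets (Å) within a residue, relative to the CA position.
_ATOM_OFFSETS = {
    "N": np.array([-0.9, 0.9, -0.4]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "C": np.array([1.0, -0.6, 0.5]),
    "O": np.array([1.5, 0.4, 1.2]),
}

# Seed of the fixed internal stream for collective-mode directions: modes
# are part of the model family, not of the per-run randomness.
_MODE_STREAM = 271828


def make_default_topology(
    n_residues_chain_a: int,
    n_residues_chain_b: int,
    first_res_a: int = 400,
    first_res_b: int = 440,
) -> Topology:
    """Two-chain backbone topology with four heavy atoms per residue.

    Default numbering places chain A at 400–460 and chain B at 440–480,
    covering the residue windows the analysis selects on.
    """
    if n_residues_chain_a < 1 or n_residues_chain_b < 1:
        raise StructureError("both chains need at least one residue")
    chain_ids: list[str] = []
    res_ids: list[int] = []
    res_names: list[str] = []
    atom_names: list[str] = []
    for chain, n_res, first in (
        ("A", n_residues_chain_a, first_res_a),
        ("B", n_residues_chain_b, first_res_b),
    ):
        for i in range(n_res):
            for name in BACKBONE_HEAVY:
                chain_ids.append(chain)
                res_ids.append(first + i)
                res_names.append("ALA")
                atom_names.append(name)
    return Topology(
        chain_ids=tuple(chain_ids),
        res_ids=tuple(res_ids),
        res_names=tuple(res_names),
        atom_names=tuple(atom_names),
    )


def base_geometry(topology: Topology) -> np.ndarray:
    """Idealized helical backbone coordinates (Å) for the two chains.

    Chain A and chain B run as parallel helices (1.5 Å rise, 100° turn)
    with chain B offset so the default probe pair sits at a realistic
    interface distance.
    """
    coords = np.empty((topology.n_atoms, 3))
    chain_offset = {"A": np.zeros(3), "B": np.array([-15.0, 12.0, 4.0])}
    chain_first: dict[str, int] = {}
    for i in range(topology.n_atoms):
        chain = topology.chain_ids[i]
        chain_first.setdefault(chain, topology.res_ids[i])
        r = topology.res_ids[i] - chain_first[chain]
        origin = chain_offset[chain] + np.array(
            [1.5 * r, 2.3 * np.sin(r * 1.745), 2.3 * np.cos(r * 1.745)]
        )
        coords[i] = origin + _ATOM_OFFSETS[topology.atom_names[i]]
    return coords


@dataclass
class GeneratorConfig:
    """Everything needed to generate one matched variant pair.

    ``state_geometries`` and ``transition_matrices`` map each variant
    label to its (n_states, n_atoms, 3) geometry stack and row-stochastic
    chain.  Defaults reproduce the reference protocol bookkeeping: ten
    replicates of 10 000 stored frames at 10 ps.
    """

    topology: Topology
    probe: ProbePair
    reference_coords: np.ndarray
    transition_matrices: dict[str, np.ndarray]
    state_geometries: dict[str, np.ndarray]
    noise_sigma: float = 0.15
    mode_sigma: float = 0.9
    n_modes: int = 3
    mode_selection: np.ndarray | None = None  # atom indices carried by the modes
    rigid_max_rotation_deg: float = 10.0
    rigid_max_translation: float = 2.0
    n_replicates: int = 10
    frames_per_replicate: int = 10_000
    frame_interval: float = 10.0  # ps
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0 or self.mode_sigma < 0:
            raise ValueError("noise scales must be non-negative")
        if self.frames_per_replicate < 2:
            raise ValueError("frames_per_replicate must be >= 2")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        shape = None
        for variant, T in self.transition_matrices.items():
            T = np.asarray(T, dtype=np.float64)
            _check_stochastic(T)
            self.transition_matrices[variant] = T
            G = np.asarray(self.state_geometries[variant], dtype=np.float64)
            if G.shape != (T.shape[0], self.topology.n_atoms, 3):
                raise ValueError(
                    f"variant {variant}: geometries shape {G.shape} does not match "
                    f"{T.shape[0]} states over {self.topology.n_atoms} atoms"
                )
            self.state_geometries[variant] = G
            if shape is None:
                shape = G.shape
            elif G.shape != shape:
                raise ValueError("all variants must share one topology and state count")

    @property
    def n_states(self) -> int:
        return next(iter(self.transition_matrices.values())).shape[0]

    @property
    def variants(self) -> tuple[str, ...]:
        return tuple(self.transition_matrices)

    @classmethod
    def default(
        cls,
        seed: int = 0,
        n_replicates: int = 10,
        frames_per_replicate: int = 10_000,
        stationary_wildtype: tuple[float, ...] = (0.4, 0.4, 0.1, 0.1),
        stationary_mutant: tuple[float, ...] = (0.1, 0.1, 0.4, 0.4),
        metastability: float = 0.85,
        planted_norm_wildtype: tuple[float, ...] = (1.75, 1.60, 1.30, 1.10),
        planted_norm_mutant: tuple[float, ...] = (1.50, 1.30, 1.05, 0.90),
        state_separation: float = 8.0,
        **overrides,
    ) -> "GeneratorConfig":
        """Build the default matched-pair configuration.

        The wild-type chain concentrates occupancy on states whose probe
        pair sits far from the reference distance (normalized 1.6–1.75),
        the mutant on states near it (0.9–1.05); ``metastability`` is the
        per-step probability of resampling nothing (self-persistence of
        the planted chain).
        """
        topology = make_default_topology(61, 41)
        probe = ProbePair("A", 427, "B", 477)
        base = base_geometry(topology)
        reference = ReferenceStructure(topology=topology, coords=base, probe=probe)
        d_ref = reference.d_ref
        n_states = len(stationary_wildtype)
        if len(stationary_mutant) != n_states:
            raise ValueError("variant stationary vectors must agree in length")

        matrices = {
            "wildtype": metastable_chain(np.asarray(stationary_wildtype), metastability),
            "mutant": metastable_chain(np.asarray(stationary_mutant), metastability),
        }
        geoms = {
            "wildtype": make_state_geometries(
                topology, base, probe,
                d_ref * np.asarray(planted_norm_wildtype), state_separation),
            "mutant": make_state_geometries(
                topology, base, probe,
                d_ref * np.asarray(planted_norm_mutant), state_separation),
        }
        af2 = np.asarray(
            [i for i in range(topology.n_atoms)
             if topology.chain_ids[i] == "B" and 460 <= topology.res_ids[i] <= 477],
            dtype=np.intp,
        )
        return cls(
            topology=topology,
            probe=probe,
            reference_coords=base.copy(),
            transition_matrices=matrices,
            state_geometries=geoms,
            mode_selection=af2,
            seed=seed,
            n_replicates=n_replicates,
            frames_per_replicate=frames_per_replicate,
            **overrides,
        )

    @classmethod
    def small_preset(cls, seed: int = 0, **overrides) -> "GeneratorConfig":
        """Desk-scale preset: 2 replicates of 500 frames per variant."""
        return cls.default(seed=seed, n_replicates=2, frames_per_replicate=500,
                           **overrides)


def metastable_chain(stationary: np.ndarray, metastability: float) -> np.ndarray:
    """Reversible chain with the given stationary distribution.

    ``T = m*I + (1-m) * 1 pi^T`` satisfies detailed balance for any
    target pi and has self-persistence ``m`` on top of the stationary
    resampling; larger ``m`` means stickier (more metastable) states.
    """
    pi = np.asarray(stationary, dtype=np.float64)
    if np.any(pi <= 0) or abs(pi.sum() - 1.0) > 1e-12:
        raise ValueError("stationary vector must be positive and sum to 1")
    if not (0.0 <= metastability < 1.0):
        raise ValueError("metastability must be in [0, 1)")
    n = pi.size
    return metastability * np.eye(n) + (1.0 - metastability) * np.tile(pi, (n, 1))


def make_state_geometries(
    topology: Topology,
    base: np.ndarray,
    probe: ProbePair,
    planted_distances: np.ndarray,
    state_separation: float = 8.0,
    af2_first: int = 460,
) -> np.ndarray:
    """Per-state geometries with exact planted probe distances.

    Each state displaces the chain-B AF2 body (residues ``af2_first``
    up to, but excluding, the probe residue) along a state-specific
    direction by ``state_separation`` Å, and rigidly shifts the probe
    residue so its Cα lies exactly at the planted distance from the
    chain-A probe Cα along their connecting line.
    """
    planted_distances = np.asarray(planted_distances, dtype=np.float64)
    if np.any(planted_distances <= 0):
        raise ValueError("planted probe distances must be positive")
    n_states = planted_distances.size
    dirs = _state_directions(n_states)
    ia, ib = probe.indices(topology)
    a_ca = base[ia]
    axis = base[ib] - a_ca
    axis = axis / np.linalg.norm(axis)
    body = np.asarray(
        [i for i in range(topology.n_atoms)
         if topology.chain_ids[i] == probe.chain_b
         and af2_first <= topology.res_ids[i]
         and topology.res_ids[i] != probe.res_b],
        dtype=np.intp,
    )
    probe_res = np.asarray(
        [i for i in range(topology.n_atoms)
         if topology.chain_ids[i] == probe.chain_b
         and topology.res_ids[i] == probe.res_b],
        dtype=np.intp,
    )
    geoms = np.repeat(base[None], n_states, axis=0)
    for s in range(n_states):
        geoms[s, body] += state_separation * dirs[s]
        target_ca = a_ca + planted_distances[s] * axis
        geoms[s, probe_res] += target_ca - base[ib]
    return geoms


def _state_directions(n_states: int) -> np.ndarray:
    """Well-separated unit directions; tetrahedral for up to 4 states,
    deterministic random beyond."""
    tetra = np.array(
        [[1.0, 1.0, 1.0], [1.0, -1.0, -1.0], [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]]
    ) / np.sqrt(3.0)
    if n_states <= 4:
        return tetra[:n_states]
    rng = np.random.default_rng(_MODE_STREAM + 1)
    extra = rng.normal(size=(n_states - 4, 3))
    extra /= np.linalg.norm(extra, axis=1, keepdims=True)
    return np.vstack([tetra, extra])


def _collective_modes(n_modes: int, atom_indices: np.ndarray) -> np.ndarray:
    """Orthonormal collective-motion directions over the chosen atoms,
    scaled to unit per-atom RMS displacement.  Drawn from a fixed
    internal stream so the model family does not change with the run
    seed."""
    n_atoms = atom_indices.size
    rng = np.random.default_rng(_MODE_STREAM)
    G = rng.normal(size=(3 * n_atoms, n_modes))
    Q, _ = np.linalg.qr(G)
    modes = Q.T.reshape(n_modes, n_atoms, 3)
    return modes * np.sqrt(n_atoms)


def _check_stochastic(T: np.ndarray) -> None:
    if T.ndim != 2 or T.shape[0] != T.shape[1]:
        raise ValueError("transition matrix must be square")
    if np.any(T < 0):
        raise ValueError("transition matrix has negative entries")
    if np.max(np.abs(T.sum(axis=1) - 1.0)) > 1e-9:
        raise ValueError("transition matrix rows must sum to 1")


def analytic_stationary(T: np.ndarray) -> np.ndarray:
    """Stationary distribution of a stochastic matrix (left eigenvector)."""
    T = np.asarray(T, dtype=np.float64)
    _check_stochastic(T)
    n = T.shape[0]
    A = np.vstack([T.T - np.eye(n), np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def sample_state_path(
    transition_matrix: np.ndarray,
    n_steps: int,
    initial_state: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Sample a Markov-chain state path of length ``n_steps``.

    ``path[0] == initial_state``; each subsequent state is drawn from the
    row of the current state.  Bit-reproducible for a fixed seed.
    """
    T = np.asarray(transition_matrix, dtype=np.float64)
    _check_stochastic(T)
    n = T.shape[0]
    if not (0 <= initial_state < n):
        raise ValueError(f"initial state {initial_state} outside [0, {n})")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cum = np.cumsum(T, axis=1)
    cum[:, -1] = 1.0  # guard round-off at the right edge
    u = rng.random(n_steps - 1)
    path = np.empty(n_steps, dtype=np.intp)
    path[0] = initial_state
    s = initial_state
    for t in range(1, n_steps):
        s = int(np.searchsorted(cum[s], u[t - 1], side="right"))
        path[t] = s
    return path


def emit_trajectory(
    state_path: np.ndarray,
    geometries: np.ndarray,
    noise_sigma: float,
    rigid_max_rotation_deg: float,
    rigid_max_translation: float,
    frame_interval: float,
    seed: int | np.random.Generator = 0,
    topology: Topology | None = None,
    modes: np.ndarray | None = None,
    mode_selection: np.ndarray | None = None,
    mode_sigma: float = 0.0,
    variant: str | None = None,
    replicate: int | None = None,
) -> Trajectory:
    """Turn a state path into coordinate frames.

    Each frame is its state geometry, plus collective-mode displacement
    (if configured), plus i.i.d. Gaussian noise on every coordinate, then
    a random proper rigid-body transform about the frame centroid.
    Frame times are 0, dt, 2 dt, ...
    """
    state_path = np.asarray(state_path, dtype=np.intp)
    geometries = np.asarray(geometries, dtype=np.float64)
    if geometries.ndim != 3:
        raise ValueError("geometries must be (n_states, n_atoms, 3)")
    if state_path.min() < 0 or state_path.max() >= geometries.shape[0]:
        raise ValueError("state path refers to a state without a geometry")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_frames = state_path.size
    n_atoms = geometries.shape[1]
    coords = geometries[state_path].copy()

    if modes is not None and mode_sigma > 0.0:
        amp = rng.normal(scale=mode_sigma, size=(n_frames, modes.shape[0]))
        displacement = np.einsum("fk,kmi->fmi", amp, modes)
        if mode_selection is None:
            coords += displacement
        else:
            coords[:, mode_selection, :] += displacement
    if noise_sigma > 0.0:
        coords += rng.normal(scale=noise_sigma, size=(n_frames, n_atoms, 3))

    max_angle = np.deg2rad(rigid_max_rotation_deg)
    if max_angle > 0.0 or rigid_max_translation > 0.0:
        axes = rng.normal(size=(n_frames, 3))
        axes /= np.linalg.norm(axes, axis=1, keepdims=True)
        angles = rng.uniform(0.0, max_angle, size=n_frames)
        rots = Rotation.from_rotvec(axes * angles[:, None])
        tdir = rng.normal(size=(n_frames, 3))
        tdir /= np.linalg.norm(tdir, axis=1, keepdims=True)
        tnorm = rng.uniform(0.0, rigid_max_translation, size=n_frames)
        centroids = coords.mean(axis=1, keepdims=True)
        centered = coords - centroids
        rotated = np.einsum("fij,fmj->fmi", rots.as_matrix(), centered)
        coords = rotated + centroids + (tdir * tnorm[:, None])[:, None, :]

    times = frame_interval * np.arange(n_frames, dtype=np.float64)
    if topology is None:
        topology = make_default_topology(1, max(1, n_atoms // 4 - 1))
        if topology.n_atoms != n_atoms:
            raise ValueError("topology required when atom count is non-default")
    return Trajectory(topology=topology, coords=coords, times=times,
                      variant=variant, replicate=replicate)


@dataclass
class PlantedTruth:
    """Ground truth of one generated dataset."""

    state_paths: dict[str, list[np.ndarray]]
    stationary: dict[str, np.ndarray]
    planted_probe_distance: dict[str, np.ndarray]
    d_ref: float

    def to_json(self, path: str | Path) -> None:
        payload = {
            "d_ref": self.d_ref,
            "stationary": {v: p.tolist() for v, p in self.stationary.items()},
            "planted_probe_distance": {
                v: d.tolist() for v, d in self.planted_probe_distance.items()
            },
            "state_paths": {
                v: [p.tolist() for p in paths]
                for v, paths in self.state_paths.items()
            },
        }
        Path(path).write_text(json.dumps(payload))


def aggregate_time_ps(config: GeneratorConfig) -> float:
    """Per-variant aggregate simulated time (ps): replicates × frames × dt.

    A replicate of F stored frames at interval dt accounts for F*dt of
    simulated time (times run dt..F*dt for duration bookkeeping even
    though frame indexing starts at t=0), so the default protocol reports
    10 × 10 000 × 10 ps = 1 µs per variant.
    """
    return config.n_replicates * config.frames_per_replicate * config.frame_interval


def make_variant_pair(
    config: GeneratorConfig,
) -> tuple[dict[str, list[Trajectory]], ReferenceStructure, PlantedTruth]:
    """Generate the full matched dataset for both variants.

    Returns per-variant trajectory lists, the reference structure with
    its probe distance, and the planted truth (paths, stationary
    distributions, exact per-state probe distances).
    """
    reference = ReferenceStructure(
        topology=config.topology,
        coords=np.asarray(config.reference_coords, dtype=np.float64),
        probe=config.probe,
    )
    modes = None
    if config.n_modes > 0 and config.mode_sigma > 0.0:
        sel = (config.mode_selection if config.mode_selection is not None
               else np.arange(config.topology.n_atoms))
        modes = _collective_modes(config.n_modes, np.asarray(sel, dtype=np.intp))

    root = np.random.SeedSequence(config.seed)
    children = root.spawn(len(config.variants) * config.n_replicates)

    ia, ib = config.probe.indices(config.topology)
    trajectories: dict[str, list[Trajectory]] = {}
    paths: dict[str, list[np.ndarray]] = {}
    stationary: dict[str, np.ndarray] = {}
    planted_d: dict[str, np.ndarray] = {}
    for v, variant in enumerate(config.variants):
        T = config.transition_matrices[variant]
        geoms = config.state_geometries[variant]
        pi = analytic_stationary(T)
        stationary[variant] = pi
        planted_d[variant] = np.linalg.norm(
            geoms[:, ib, :] - geoms[:, ia, :], axis=1
        )
        trajectories[variant] = []
        paths[variant] = []
        for r in range(config.n_replicates):
            child = children[v * config.n_replicates + r]
            path_rng, emit_rng = (np.random.default_rng(s) for s in child.spawn(2))
            initial = int(path_rng.choice(config.n_states, p=pi))
            path = sample_state_path(T, config.frames_per_replicate, initial,
                                     seed=path_rng)
            traj = emit_trajectory(
                path, geoms,
                noise_sigma=config.noise_sigma,
                rigid_max_rotation_deg=config.rigid_max_rotation_deg,
                rigid_max_translation=config.rigid_max_translation,
                frame_interval=config.frame_interval,
                seed=emit_rng,
                topology=config.topology,
                modes=modes,
                mode_selection=config.mode_selection,
                mode_sigma=config.mode_sigma,
                variant=variant,
                replicate=r,
            )
            trajectories[variant].append(traj)
            paths[variant].append(path)

    truth = PlantedTruth(
        state_paths=paths,
        stationary=stationary,
        planted_probe_distance=planted_d,
        d_ref=reference.d_ref,
    )
    return trajectories, reference, truth


def write_dataset(
    outdir: str | Path,
    trajectories: dict[str, list[Trajectory]],
    reference: ReferenceStructure,
    truth: PlantedTruth,
) -> None:
    """Write trajectories as multi-model PDBs, the reference as a
    single-model PDB, and the planted truth as JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for variant, trajs in trajectories.items():
        for traj in trajs:
            write_multimodel_pdb(
                traj, outdir / f"{variant}_rep{traj.replicate:02d}.pdb"
            )
    write_reference_pdb(reference, outdir / "reference.pdb")
    truth.to_json(outdir / "planted_truth.json")
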
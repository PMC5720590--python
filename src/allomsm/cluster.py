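"""Hybrid k-centers/k-medoids clustering in a shared conformational state space.

Frames from every variant and replicate are pooled in one deterministic
order (variant, replicate, frame index) and clustered together, so both
variants' occupancies are expressed over one cluster index set.  Greedy
k-centers grows centers until the covering radius falls below the cutoff
(1 Å by default); k-medoids refinement (50 iterations by default) then
swaps each medoid for the member minimizing the within-cluster distance
sum and reassigns, which never increases the objective.

The metric is pluggable: the production metric is minimum RMSD over the
selected backbone-heavy atoms after optimal superposition, but any
object with a ``to_many(frames, ref) -> distances`` method works, which
the tests exploit with scalar surrogate metrics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Protocol, Sequence

import numpy as np

from .superpose import rmsd_to_many

logger = logging.getLogger(__name__)

__all__ = ["Metric", "RmsdMetric", "FrameRef", "ClusterModel",
           "kcenters", "kmedoids_refine", "assign"]

#: Distances within this tolerance are ties; ties go to the lower index.
TIE_TOL = 1e-9


class Metric(Protocol):
    def to_many(self, frames: np.ndarray, ref: np.ndarray) -> np.ndarray:
        """Distance from each frame in a stack to one reference frame."""
        ...


@dataclass(frozen=True)
class RmsdMetric:
    """Minimum RMSD over a fixed atom selection after Kabsch superposition
    on that same selection (both residue windows jointly)."""

    selection_indices: np.ndarray

    def to_many(self, frames: np.ndarray, ref: np.ndarray) -> np.ndarray:
        sel = self.selection_indices
        return rmsd_to_many(frames[:, sel, :], ref[sel])

    def describe(self) -> dict:
        return {
            "kind": "min_rmsd",
            "superposition": "kabsch_on_full_selection",
            "n_atoms": int(len(self.selection_indices)),
        }


@dataclass(frozen=True, order=True)
class FrameRef:
    """Stable identity of one pooled frame."""

    variant: str
    replicate: int
    frame_index: int


@dataclass
class ClusterModel:
    """Medoid-defined microstates plus per-frame assignments.

    ``medoid_pool_indices`` index into the pooled frame order used at fit
    time; ``medoid_refs`` carry the corresponding (variant, replicate,
    frame) identities when the pool provided them.
    """

    metric: Metric
    cutoff: float
    medoid_pool_indices: np.ndarray  # (k,)
    medoid_coords: np.ndarray  # (k, ...) copies of the medoid frames
    assignments: np.ndarray  # (n,) cluster index per pooled frame
    distances: np.ndarray  # (n,) distance to assigned medoid
    medoid_refs: list[FrameRef] | None = None
    n_iterations: int = 0
    objective_history: list[float] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return len(self.medoid_pool_indices)

    @property
    def radius(self) -> float:
        """Achieved covering radius (max distance to assigned medoid)."""
        return float(self.distances.max())

    @property
    def objective(self) -> float:
        """Total within-cluster distance sum."""
        return float(self.distances.sum())


def _assign_with_ties(D: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-column assignment; ties within TIE_TOL go to the lower index."""
    best = D.min(axis=1)
    assignment = (D <= best[:, None] + TIE_TOL).argmax(axis=1)
    return assignment.astype(np.intp), D[np.arange(D.shape[0]), assignment]


def kcenters(
    frames: np.ndarray,
    cutoff: float,
    metric: Metric,
    frame_refs: Sequence[FrameRef] | None = None,
) -> ClusterModel:
    """Greedy k-centers until the covering radius is at or below ``cutoff``.

    The first center is the first frame in pool order; each subsequent
    center is the frame farthest from its nearest existing center.  Fully
    deterministic for a given pool order.
    """
    frames = np.asarray(frames, dtype=np.float64)
    n = frames.shape[0]
    if n == 0:
        raise ValueError("cannot cluster an empty frame pool")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")

    centers = [0]
    columns = [metric.to_many(frames, frames[0])]
    dmin = columns[0].copy()
    while dmin.max() > cutoff:
        new = int(dmin.argmax())
        centers.append(new)
        col = metric.to_many(frames, frames[new])
        columns.append(col)
        np.minimum(dmin, col, out=dmin)
    D = np.stack(columns, axis=1)
    assignment, dist = _assign_with_ties(D)
    medoid_idx = np.asarray(centers, dtype=np.intp)
    refs = [frame_refs[i] for i in centers] if frame_refs is not None else None
    return ClusterModel(
        metric=metric,
        cutoff=float(cutoff),
        medoid_pool_indices=medoid_idx,
        medoid_coords=frames[medoid_idx].copy(),
        assignments=assignment,
        distances=dist,
        medoid_refs=refs,
    )


def kmedoids_refine(
    frames: np.ndarray,
    model: ClusterModel,
    n_iterations: int,
    seed: int | None = None,
    max_exact: int = 4000,
    frame_refs: Sequence[FrameRef] | None = None,
) -> ClusterModel:
    """k-medoids refinement of an existing model.

    Each iteration proposes, per cluster, the member minimizing the sum
    of within-cluster distances (exhaustively up to ``max_exact``
    members, on a seeded random subsample beyond that) and accepts it
    only if it strictly lowers the cluster cost; all frames are then
    reassigned to their nearest medoid.  The objective is non-increasing
    across iterations.  Once medoids and assignments stop changing the
    model is a fixed point and the remaining iterations are no-ops.
    Empty clusters after reassignment are dropped with a warning.
    """
    if n_iterations < 0:
        raise ValueError("n_iterations must be >= 0")
    frames = np.asarray(frames, dtype=np.float64)
    n = frames.shape[0]
    if model.assignments.shape != (n,):
        raise ValueError("model assignments do not match the frame pool")
    rng = np.random.default_rng(seed)

    medoids = list(int(i) for i in model.medoid_pool_indices)
    D = np.stack([model.metric.to_many(frames, frames[m]) for m in medoids], axis=1)
    assignment, dist = _assign_with_ties(D)
    history: list[float] = []
    converged = False
    iterations_run = 0

    for _ in range(n_iterations):
        iterations_run += 1
        if converged:
            history.append(float(dist.sum()))
            continue
        changed = False
        for c in range(len(medoids)):
            members = np.flatnonzero(assignment == c)
            if members.size == 0:
                continue
            if members.size > max_exact:
                cand = rng.choice(members, size=max_exact, replace=False)
                if medoids[c] not in cand:
                    cand = np.append(cand, medoids[c])
                cand = np.sort(cand)
            else:
                cand = members
            member_coords = frames[members]
            costs = np.array(
                [model.metric.to_many(member_coords, frames[x]).sum() for x in cand]
            )
            cur_pos = np.flatnonzero(cand == medoids[c])
            cur_cost = (
                costs[cur_pos[0]]
                if cur_pos.size
                else model.metric.to_many(member_coords, frames[medoids[c]]).sum()
            )
            best = costs.min()
            best_idx = int(cand[(costs <= best + TIE_TOL).argmax()])
            if best < cur_cost - TIE_TOL and best_idx != medoids[c]:
                medoids[c] = best_idx
                D[:, c] = model.metric.to_many(frames, frames[best_idx])
                changed = True
        new_assignment, new_dist = _assign_with_ties(D)
        # drop clusters emptied by reassignment
        occupied = np.unique(new_assignment)
        if occupied.size < len(medoids):
            dropped = sorted(set(range(len(medoids))) - set(occupied.tolist()))
            logger.warning("dropping empty clusters %s during refinement", dropped)
            remap = -np.ones(len(medoids), dtype=np.intp)
            remap[occupied] = np.arange(occupied.size)
            medoids = [medoids[i] for i in occupied]
            D = D[:, occupied]
            new_assignment = remap[new_assignment]
            changed = True
        if not changed and np.array_equal(new_assignment, assignment):
            converged = True
        assignment, dist = new_assignment, new_dist
        history.append(float(dist.sum()))

    medoid_idx = np.asarray(medoids, dtype=np.intp)
    medoid_refs = [frame_refs[i] for i in medoids] if frame_refs is not None else None
    return replace(
        model,
        medoid_pool_indices=medoid_idx,
        medoid_coords=frames[medoid_idx].copy(),
        assignments=assignment,
        distances=dist,
        medoid_refs=medoid_refs,
        n_iterations=model.n_iterations + iterations_run,
        objective_history=list(model.objective_history) + history,
    )


def assign(frames: np.ndarray, model: ClusterModel) -> tuple[np.ndarray, np.ndarray]:
    """Out-of-sample nearest-medoid assignment under the model's metric.

    Returns (cluster indices, distances).  Ties within tolerance go to
    the lower cluster index.
    """
    frames = np.asarray(frames, dtype=np.float64)
    D = np.stack(
        [model.metric.to_many(frames, model.medoid_coords[c])
         for c in range(model.n_clusters)],
        axis=1,
    )
    return _assign_with_ties(D)
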
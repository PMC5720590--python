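"""Crystal-normalized probe-pair distances and between-variant comparison.

The allosteric readout is the Cα–Cα distance between the mutated-site
residue on the RXRA-like chain and the terminal tyrosine of the
PPARG-like chain (defaults: chain A residue 427, chain B residue 477),
evaluated on one representative frame — the medoid — of each selected
top-occupancy microstate, and normalized by the same distance in the
agonist-crystal reference structure.  Being an intra-frame distance it
needs no superposition.  Variants are compared with a two-tailed
pooled-variance Student's t test.

A secondary readout uses anchor superposition (helix 11) onto the
reference and reports how far the probe Cα has moved from its reference
position — the displacement-style view of the same allosteric shift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial.distance import jensenshannon

from .cluster import ClusterModel, FrameRef
from .structure import ProbePair, ReferenceStructure

__all__ = ["TTestResult", "OverlapSummary", "microstate_representative",
           "probe_distance", "normalize_distance", "compare_variants",
           "occupancy_overlap", "probe_displacement"]


@dataclass(frozen=True)
class TTestResult:
    """Two-sample pooled-variance Student's t, two-tailed."""

    t: float
    df: int
    p: float
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int
    degenerate_variance: bool = False


@dataclass(frozen=True)
class OverlapSummary:
    """How much two occupancy distributions share the cluster set."""

    n_exclusive_a: int
    n_exclusive_b: int
    n_shared: int
    jensen_shannon_nats: float

    @property
    def n_occupied(self) -> int:
        return self.n_exclusive_a + self.n_exclusive_b + self.n_shared


def microstate_representative(model: ClusterModel, microstate: int) -> FrameRef:
    """The medoid frame reference of one microstate (deterministic)."""
    if not (0 <= microstate < model.n_clusters):
        raise ValueError(f"microstate {microstate} out of range")
    if not np.any(model.assignments == microstate):
        raise ValueError(f"microstate {microstate} is empty")
    if model.medoid_refs is None:
        raise ValueError("model carries no frame references")
    return model.medoid_refs[microstate]


def probe_distance(coords: np.ndarray, topology, pair: ProbePair) -> float:
    """Euclidean Cα–Cα distance (Å) inside one frame."""
    ia, ib = pair.indices(topology)
    coords = np.asarray(coords, dtype=np.float64)
    return float(np.linalg.norm(coords[ia] - coords[ib]))


def normalize_distance(d: float, reference: ReferenceStructure) -> float:
    """Probe distance as a multiple of the reference (crystal) distance."""
    if d <= 0:
        raise ValueError("distance must be positive")
    d_ref = reference.d_ref
    if d_ref <= 0:
        raise ValueError("reference distance must be positive")
    return d / d_ref


def probe_displacement(
    frame_coords: np.ndarray,
    frame_topology,
    reference: ReferenceStructure,
    anchor,
    which: str = "b",
) -> float:
    """Displacement (Å) of one probe Cα from its reference position after
    anchor superposition — the secondary, displacement-style readout."""
    from .superpose import superpose_onto_anchor

    fitted = superpose_onto_anchor(frame_coords, frame_topology, reference, anchor)
    ia, ib = reference.probe.indices(reference.topology)
    ja, jb = reference.probe.indices(frame_topology)
    if which == "a":
        return float(np.linalg.norm(fitted[ja] - reference.coords[ia]))
    if which == "b":
        return float(np.linalg.norm(fitted[jb] - reference.coords[ib]))
    raise ValueError("which must be 'a' or 'b'")


def compare_variants(
    values_a: np.ndarray, values_b: np.ndarray, welch: bool = False
) -> TTestResult:
    """Two-tailed Student's t test between two samples.

    Pooled-variance by default (matching the classical "Student's t");
    ``welch=True`` switches to the unequal-variance form.  Degenerate
    case: zero variance in both samples with unequal means is reported
    as p = 0 with a flag (t is infinite); equal constant samples give
    t = 0, p = 1.
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    mean_a, mean_b = float(a.mean()), float(b.mean())
    sd_a = float(a.std(ddof=1))
    sd_b = float(b.std(ddof=1))
    df = a.size + b.size - 2
    if sd_a == 0.0 and sd_b == 0.0:
        if mean_a == mean_b:
            return TTestResult(0.0, df, 1.0, mean_a, mean_b, sd_a, sd_b,
                               a.size, b.size)
        t = np.inf if mean_a > mean_b else -np.inf
        return TTestResult(float(t), df, 0.0, mean_a, mean_b, sd_a, sd_b,
                           a.size, b.size, degenerate_variance=True)
    res = stats.ttest_ind(a, b, equal_var=not welch)
    if welch:
        df = int(np.floor(res.df)) if hasattr(res, "df") else df
    return TTestResult(float(res.statistic), df, float(res.pvalue),
                       mean_a, mean_b, sd_a, sd_b, a.size, b.size)


def occupancy_overlap(
    pi_a: np.ndarray, pi_b: np.ndarray, floor: float = 0.0
) -> OverlapSummary:
    """Exclusive/shared cluster counts at an occupancy floor plus the
    Jensen–Shannon divergence (nats) between the two distributions."""
    pi_a = np.asarray(pi_a, dtype=np.float64)
    pi_b = np.asarray(pi_b, dtype=np.float64)
    if pi_a.shape != pi_b.shape:
        raise ValueError("occupancy distributions must share the cluster set")
    in_a = pi_a > floor
    in_b = pi_b > floor
    jsd = float(jensenshannon(pi_a, pi_b, base=np.e) ** 2)
    # guard tiny negative round-off and the exact-equality NaN-free path
    jsd = min(max(jsd, 0.0), float(np.log(2.0)))
    return OverlapSummary(
        n_exclusive_a=int(np.sum(in_a & ~in_b)),
        n_exclusive_b=int(np.sum(in_b & ~in_a)),
        n_shared=int(np.sum(in_a & in_b)),
        jensen_shannon_nats=jsd,
    )
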
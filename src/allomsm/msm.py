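"""Per-variant Markov state model estimation from cluster assignments.

Transitions are counted with a sliding window at a fixed lag inside each
replicate (never across replicate boundaries), symmetrized with the
transpose estimator C~ = (C + C^T)/2, and row-normalized into a
transition matrix.  For the transpose estimator the stationary
distribution has the closed form pi_i = rowsum_i(C~)/total(C~), and
detailed balance pi_i T_ij = pi_j T_ji holds exactly, not just in the
large-sample limit.

No ergodic trimming is applied by default, so disconnected microstates
are legal: a state with no counts gets an identity row in T (flagged)
and zero stationary weight.  The transpose estimator is consistent for
reversible chains; for an irreversible chain it converges to the
row-normalized additive symmetrization of the stationary flux — which
has the same stationary distribution as the true chain, but not the
same transition matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["CountsMatrix", "MSModel", "count_transitions", "symmetrize_transpose",
           "transition_matrix", "stationary_distribution", "build_msm",
           "top_occupied", "raw_occupancy"]


@dataclass
class CountsMatrix:
    """Ordered transition counts over the shared cluster index set."""

    counts: np.ndarray  # (k, k) non-negative integers
    lag: int  # in stored frames
    lag_ps: float | None = None
    variant: str | None = None
    replicate_lengths: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("counts must be square")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.lag < 1:
            raise ValueError("lag must be >= 1 frame")

    @property
    def n_states(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class MSModel:
    """Transpose-estimated MSM: symmetrized counts, T, and pi."""

    counts: CountsMatrix
    sym_counts: np.ndarray  # (k, k), half-integer valued
    transition: np.ndarray  # (k, k), row-stochastic
    stationary: np.ndarray  # (k,)
    identity_rows: np.ndarray  # (k,) bool; True where a zero-count row was patched
    ergodic_trim_applied: bool = False


def count_transitions(
    assignment_sequences: Sequence[np.ndarray],
    n_clusters: int,
    lag: int = 1,
    lag_ps: float | None = None,
    variant: str | None = None,
) -> CountsMatrix:
    """Sliding-window transition counts at the given lag.

    Each replicate sequence contributes ``len(seq) - lag`` ordered pairs
    (state at t, state at t + lag); replicate boundaries contribute
    nothing.
    """
    if lag < 1:
        raise ValueError("lag must be >= 1 frame")
    C = np.zeros((n_clusters, n_clusters), dtype=np.int64)
    lengths = []
    for r, seq in enumerate(assignment_sequences):
        seq = np.asarray(seq, dtype=np.intp)
        if seq.ndim != 1:
            raise ValueError(f"replicate {r}: assignments must be 1-D")
        if seq.size < lag + 1:
            raise ValueError(
                f"replicate {r} has {seq.size} frames, too short for lag {lag}"
            )
        if seq.min() < 0 or seq.max() >= n_clusters:
            raise ValueError(f"replicate {r}: assignment outside [0, {n_clusters})")
        np.add.at(C, (seq[:-lag], seq[lag:]), 1)
        lengths.append(int(seq.size))
    return CountsMatrix(counts=C, lag=lag, lag_ps=lag_ps, variant=variant,
                        replicate_lengths=tuple(lengths))


def symmetrize_transpose(counts: CountsMatrix | np.ndarray) -> np.ndarray:
    """Transpose symmetrization C~ = (C + C^T) / 2."""
    C = counts.counts if isinstance(counts, CountsMatrix) else np.asarray(counts)
    return (C + C.T) / 2.0


def transition_matrix(sym_counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-normalize symmetric counts into a stochastic matrix.

    Zero-count rows (disconnected states, legal because no ergodic trim
    is applied) become identity rows; returns (T, identity_row_mask).
    """
    Cs = np.asarray(sym_counts, dtype=np.float64)
    if np.any(Cs < 0):
        raise ValueError("symmetrized counts must be non-negative")
    rowsum = Cs.sum(axis=1)
    zero = rowsum == 0.0
    T = np.zeros_like(Cs)
    nz = ~zero
    T[nz] = Cs[nz] / rowsum[nz, None]
    T[zero, zero] = 1.0
    return T, zero


def stationary_distribution(sym_counts: np.ndarray) -> np.ndarray:
    """Stationary distribution of the transpose estimator.

    For symmetric counts the reversible stationary distribution is exactly
    the normalized row sums; disconnected (zero-count) states get pi = 0.
    """
    Cs = np.asarray(sym_counts, dtype=np.float64)
    total = Cs.sum()
    if total <= 0:
        raise ValueError("cannot estimate a stationary distribution from zero counts")
    return Cs.sum(axis=1) / total


def build_msm(counts: CountsMatrix) -> MSModel:
    """Counts -> symmetrized counts -> T and pi, with the no-trim bookkeeping."""
    Cs = symmetrize_transpose(counts)
    T, zero = transition_matrix(Cs)
    pi = stationary_distribution(Cs)
    return MSModel(counts=counts, sym_counts=Cs, transition=T,
                   stationary=pi, identity_rows=zero)


def raw_occupancy(assignment_sequences: Sequence[np.ndarray], n_clusters: int) -> np.ndarray:
    """Raw frame-count occupancy over the shared cluster set (the flagged
    alternative to MSM stationary populations)."""
    counts = np.zeros(n_clusters, dtype=np.float64)
    for seq in assignment_sequences:
        np.add.at(counts, np.asarray(seq, dtype=np.intp), 1.0)
    return counts / counts.sum()


def top_occupied(pi: np.ndarray, fraction: float) -> np.ndarray:
    """Indices of the most-occupied microstates.

    Ranks states by occupancy descending (ties to the lower index) and
    selects the first ceil(fraction * number-of-nonzero-occupancy states).
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    pi = np.asarray(pi, dtype=np.float64)
    n_nonzero = int(np.count_nonzero(pi))
    if n_nonzero == 0:
        raise ValueError("no state has nonzero occupancy")
    k = math.ceil(fraction * n_nonzero)
    order = np.lexsort((np.arange(pi.size), -pi))
    return order[:k]
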
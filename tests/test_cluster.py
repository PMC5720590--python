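"""k-centers coverage, k-medoids refinement, planted-state recovery."""

from dataclasses import dataclass

import numpy as np
import pytest

from allomsm.cluster import (
    FrameRef,
    RmsdMetric,
    assign,
    kcenters,
    kmedoids_refine,
)
from conftest import random_coords
from oracles import exhaustive_medoid


@dataclass(frozen=True)
class AbsMetric:
    """Scalar surrogate metric: absolute difference of 1-point 'frames'."""

    def to_many(self, frames, ref):
        return np.abs(frames[:, 0, 0] - ref[0, 0])


def scalar_frames(values):
    return np.asarray(values, dtype=float).reshape(-1, 1, 1)


def planted_pool(rng, n_states=3, per_state=40, separation=30.0, noise=0.2,
                 n_atoms=12):
    """Frames around well-separated state geometries; labels returned."""
    base = random_coords(rng, n_atoms)
    # per-state internal deformation fields: translation-free and scaled to a
    # per-atom RMS of `separation`, so the states differ in shape (min-RMSD
    # is invariant to rigid motion, a translated copy would not separate)
    fields = rng.normal(size=(n_states, n_atoms, 3))
    fields -= fields.mean(axis=1, keepdims=True)
    fields /= np.sqrt((fields ** 2).sum(axis=(1, 2), keepdims=True) / n_atoms)
    geoms = np.stack([base + separation * fields[s] for s in range(n_states)])
    labels = np.repeat(np.arange(n_states), per_state)
    frames = geoms[labels] + rng.normal(scale=noise,
                                        size=(len(labels), n_atoms, 3))
    return frames, labels, geoms


class TestKCenters:
    def test_single_frame_single_cluster(self):
        rng = np.random.default_rng(0)
        frames = random_coords(rng, 5)[None]
        model = kcenters(frames, 1.0, RmsdMetric(np.arange(5)))
        assert model.n_clusters == 1
        assert model.radius == pytest.approx(0.0, abs=1e-12)

    def test_identical_frames_collapse_to_one_cluster(self):
        rng = np.random.default_rng(1)
        frame = random_coords(rng, 5)
        frames = np.repeat(frame[None], 10, axis=0)
        model = kcenters(frames, 0.5, RmsdMetric(np.arange(5)))
        assert model.n_clusters == 1
        assert model.radius <= 1e-6  # SVD floating-point noise only

    def test_coverage_radius_bounded_by_cutoff(self):
        rng = np.random.default_rng(2)
        frames, _, _ = planted_pool(rng, separation=6.0, noise=1.0)
        cutoff = 1.0
        model = kcenters(frames, cutoff, RmsdMetric(np.arange(frames.shape[1])))
        assert model.radius <= cutoff
        # every frame closer to its medoid than to any other
        metric = RmsdMetric(np.arange(frames.shape[1]))
        D = np.stack([metric.to_many(frames, frames[m])
                      for m in model.medoid_pool_indices], axis=1)
        best = D.min(axis=1)
        chosen = D[np.arange(len(frames)), model.assignments]
        assert np.all(chosen <= best + 1e-9)

    def test_planted_states_recovered_exactly(self):
        """Separation 10x the cutoff and sub-cutoff noise: clusters must
        equal the planted partition, verified by nearest-geometry labels."""
        rng = np.random.default_rng(3)
        frames, labels, geoms = planted_pool(rng, separation=30.0, noise=0.15)
        metric = RmsdMetric(np.arange(frames.shape[1]))
        from allomsm.superpose import rmsd_min

        for i in range(3):
            for j in range(i + 1, 3):
                assert rmsd_min(geoms[i], geoms[j]) >= 10.0
        model = kcenters(frames, 1.0, metric)
        assert model.n_clusters == 3
        # exhaustive nearest-geometry labelling is the oracle
        oracle = np.argmin(
            np.stack([metric.to_many(frames, g) for g in geoms], axis=1), axis=1)
        assert np.array_equal(oracle, labels)
        # cluster ids and planted labels agree up to relabelling
        mapping = {}
        for c, lab in zip(model.assignments, labels):
            mapping.setdefault(c, lab)
            assert mapping[c] == lab
        assert len(mapping) == 3

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            kcenters(np.empty((0, 4, 3)), 1.0, RmsdMetric(np.arange(4)))


class TestKMedoids:
    def test_one_dimensional_surrogate_converges_to_true_medoids(self):
        """{0,1,2,10,11,12} with centers {0,10} must settle on {1,11}."""
        frames = scalar_frames([0, 1, 2, 10, 11, 12])
        metric = AbsMetric()
        start = kcenters(frames, 5.0, metric)
        assert start.n_clusters == 2
        refined = kmedoids_refine(frames, start, n_iterations=5, seed=0)
        assert sorted(frames[refined.medoid_pool_indices][:, 0, 0]) == [1.0, 11.0]
        # exhaustive oracle per cluster
        for c in range(refined.n_clusters):
            members = np.flatnonzero(refined.assignments == c)
            best = exhaustive_medoid(
                frames, members, lambda a, b: abs(a[0, 0] - b[0, 0]))
            assert refined.medoid_pool_indices[c] == best

    def test_zero_iterations_is_identity(self):
        frames = scalar_frames([0, 1, 2, 10, 11, 12])
        start = kcenters(frames, 5.0, AbsMetric())
        out = kmedoids_refine(frames, start, n_iterations=0)
        assert np.array_equal(out.medoid_pool_indices, start.medoid_pool_indices)
        assert np.array_equal(out.assignments, start.assignments)

    def test_optimal_medoids_are_a_fixed_point(self):
        frames = scalar_frames([0, 1, 2, 10, 11, 12])
        start = kcenters(frames, 5.0, AbsMetric())
        once = kmedoids_refine(frames, start, n_iterations=5, seed=0)
        again = kmedoids_refine(frames, once, n_iterations=7, seed=1)
        assert np.array_equal(once.medoid_pool_indices, again.medoid_pool_indices)
        assert np.array_equal(once.assignments, again.assignments)

    def test_objective_monotone_and_deterministic(self):
        rng = np.random.default_rng(4)
        frames, _, _ = planted_pool(rng, separation=4.0, noise=1.2, per_state=30)
        metric = RmsdMetric(np.arange(frames.shape[1]))
        start = kcenters(frames, 1.5, metric)
        a = kmedoids_refine(frames, start, n_iterations=50, seed=11)
        b = kmedoids_refine(frames, start, n_iterations=50, seed=11)
        hist = np.array(a.objective_history)
        assert len(hist) == 50
        assert np.all(np.diff(hist) <= 1e-9)
        assert np.array_equal(a.assignments, b.assignments)
        assert np.array_equal(a.medoid_pool_indices, b.medoid_pool_indices)

    def test_refinement_never_increases_cluster_count(self):
        rng = np.random.default_rng(5)
        frames, _, _ = planted_pool(rng, separation=3.0, noise=1.5, per_state=25)
        metric = RmsdMetric(np.arange(frames.shape[1]))
        start = kcenters(frames, 2.0, metric)
        refined = kmedoids_refine(frames, start, n_iterations=20, seed=0)
        assert refined.n_clusters <= start.n_clusters


class TestAssign:
    def test_medoid_frames_map_to_their_own_cluster(self):
        rng = np.random.default_rng(6)
        frames, _, _ = planted_pool(rng)
        metric = RmsdMetric(np.arange(frames.shape[1]))
        model = kcenters(frames, 1.0, metric)
        clusters, dists = assign(frames[model.medoid_pool_indices], model)
        assert np.array_equal(clusters, np.arange(model.n_clusters))
        assert np.max(dists) <= 1e-6  # SVD floating-point noise only

    def test_tie_breaks_toward_lower_cluster_index(self):
        frames = scalar_frames([0.0, 10.0])
        model = kcenters(frames, 4.0, AbsMetric())
        clusters, _ = assign(scalar_frames([5.0]), model)
        assert clusters[0] == 0

    def test_frame_refs_travel_with_medoids(self):
        rng = np.random.default_rng(7)
        frames, _, _ = planted_pool(rng, per_state=10)
        refs = [FrameRef("wildtype", 0, i) for i in range(len(frames))]
        metric = RmsdMetric(np.arange(frames.shape[1]))
        model = kcenters(frames, 1.0, metric, frame_refs=refs)
        model = kmedoids_refine(frames, model, 5, seed=0, frame_refs=refs)
        for c, ref in enumerate(model.medoid_refs):
            assert refs[model.medoid_pool_indices[c]] == ref
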
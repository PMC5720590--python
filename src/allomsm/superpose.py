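"""Optimal rigid-body superposition (Kabsch) and minimum RMSD.

All RMSDs in the clustering state space are computed *after* optimal
superposition of the selected atoms: the generator applies a random
rigid-body transform to every frame, and a 1 Å cluster cutoff is only
meaningful once that global motion has been removed.  Rotations are
restricted to proper ones (determinant +1) by sign-correcting the
smallest singular direction, so mirror images are never matched.
Atoms are equally weighted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SuperposeError", "RigidTransform", "kabsch", "rmsd_min",
           "rmsd_to_many", "superpose_onto_anchor"]


class SuperposeError(ValueError):
    pass


@dataclass(frozen=True)
class RigidTransform:
    """Proper rotation + translation, applied as ``x -> R x + t``."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=np.float64)
        t = np.asarray(self.translation, dtype=np.float64)
        if R.shape != (3, 3) or t.shape != (3,):
            raise SuperposeError("rotation must be 3x3 and translation length 3")
        if np.max(np.abs(R @ R.T - np.eye(3))) > 1e-8:
            raise SuperposeError("rotation matrix is not orthogonal")
        if abs(np.linalg.det(R) - 1.0) > 1e-8:
            raise SuperposeError("rotation matrix is not proper (det != +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=np.float64)
        return coords @ self.rotation.T + self.translation

    def to_dict(self) -> dict:
        return {"rotation": self.rotation.tolist(),
                "translation": self.translation.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(np.asarray(d["rotation"]), np.asarray(d["translation"]))


def _check_coords(coords: np.ndarray, label: str) -> np.ndarray:
    coords = np.asarray(coords, dtype=np.float64)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise SuperposeError(f"{label} must have shape (n_atoms, 3)")
    if coords.shape[0] < 3:
        raise SuperposeError("superposition needs at least 3 atoms")
    return coords


def _check_nondegenerate(centered: np.ndarray, label: str) -> None:
    # Collinear (or coincident) point sets leave the rotation about the
    # common axis undetermined; reject them.
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] <= 1e-9 * max(s[0], 1.0):
        raise SuperposeError(f"{label} coordinates are (near-)collinear; "
                             "rotation is underdetermined")


def kabsch(moving: np.ndarray, target: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares fit of ``moving`` onto ``target``.

    Returns the proper rigid transform minimizing the RMSD and that
    minimized RMSD (Å).
    """
    moving = _check_coords(moving, "moving")
    target = _check_coords(target, "target")
    if moving.shape != target.shape:
        raise SuperposeError(
            f"atom count mismatch: {moving.shape[0]} vs {target.shape[0]}"
        )
    cm = moving.mean(axis=0)
    ct = target.mean(axis=0)
    a = moving - cm
    b = target - ct
    _check_nondegenerate(a, "moving")
    _check_nondegenerate(b, "target")

    H = a.T @ b
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    n = moving.shape[0]
    e0 = np.sum(a * a) + np.sum(b * b)
    msd = (e0 - 2.0 * (S[0] + S[1] + d * S[2])) / n
    rmsd = float(np.sqrt(max(msd, 0.0)))
    transform = RigidTransform(rotation=R, translation=ct - R @ cm)
    return transform, rmsd


def rmsd_min(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    selection_indices: np.ndarray | None = None,
) -> float:
    """Kabsch-minimized RMSD between two frames, optionally restricted to
    selected atoms.  Symmetric in its arguments to numerical precision."""
    frame_a = np.asarray(frame_a, dtype=np.float64)
    frame_b = np.asarray(frame_b, dtype=np.float64)
    if selection_indices is not None:
        frame_a = frame_a[selection_indices]
        frame_b = frame_b[selection_indices]
    _, rmsd = kabsch(frame_a, frame_b)
    return rmsd


def rmsd_to_many(frames: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Minimum RMSD of each frame in a stack ``(n, m, 3)`` to one
    reference ``(m, 3)``, vectorized over frames.

    Matches :func:`rmsd_min` frame-by-frame; degeneracy checks are left
    to the scalar path (the clustering pool is always 3-dimensional).
    """
    frames = np.asarray(frames, dtype=np.float64)
    ref = np.asarray(ref, dtype=np.float64)
    if frames.ndim != 3 or frames.shape[1:] != ref.shape:
        raise SuperposeError("frames must have shape (n, m, 3) matching ref (m, 3)")
    m = ref.shape[0]
    a = frames - frames.mean(axis=1, keepdims=True)
    b = ref - ref.mean(axis=0)
    H = np.einsum("nmi,mj->nij", a, b)
    S = np.linalg.svd(H, compute_uv=False)
    det = np.linalg.det(H)
    sign = np.where(det < 0.0, -1.0, 1.0)
    e0 = np.einsum("nmi,nmi->n", a, a) + np.sum(b * b)
    msd = (e0 - 2.0 * (S[:, 0] + S[:, 1] + sign * S[:, 2])) / m
    return np.sqrt(np.clip(msd, 0.0, None))


def superpose_onto_anchor(
    frame_coords: np.ndarray,
    frame_topology,
    reference,
    anchor,
) -> np.ndarray:
    """Transform a whole frame by the rigid fit computed on anchor atoms only.

    Fitting the helix-11 anchor and carrying the rest of the frame along
    makes the displacement of the AF2 region relative to the reference
    directly visible: anchor atoms land at their Kabsch minimum, the
    probe region keeps whatever internal displacement it has.
    """
    from .structure import resolve_selection

    idx_frame = resolve_selection(frame_topology, anchor)
    idx_ref = resolve_selection(reference.topology, anchor)
    if len(idx_frame) != len(idx_ref):
        raise SuperposeError("anchor resolves to different atom counts")
    transform, _ = kabsch(frame_coords[idx_frame], reference.coords[idx_ref])
    return transform.apply(frame_coords)
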
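"""Topologies, trajectories and plain-text multi-model PDB input/output.

Conformational ensembles are exchanged as multi-model PDB files, one
MODEL/ENDMDL block per stored frame, with a small JSON sidecar
(``<file>.json``) carrying the frame interval and the variant/replicate
labels.  Residue numbers are taken verbatim from the file — there is no
re-indexing — and residue ranges in selections are inclusive on both
ends, matching the author-style numbering conventions of structural
biology papers.  Files containing alternate locations or insertion codes
are rejected outright: silently picking one conformer is exactly the
kind of topology drift this module exists to catch.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "BACKBONE_HEAVY",
    "StructureError",
    "PdbFormatError",
    "TopologyMismatchError",
    "Topology",
    "AtomSelection",
    "Trajectory",
    "ProbePair",
    "ReferenceStructure",
    "resolve_selection",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "read_reference_pdb",
    "write_reference_pdb",
]

#: Atom-name class used for the clustering state space.
BACKBONE_HEAVY = ("N", "CA", "C", "O")


class StructureError(ValueError):
    """Base error for structural containers and PDB handling."""


class PdbFormatError(StructureError):
    """A PDB record could not be parsed; the message carries the line number."""


class TopologyMismatchError(StructureError):
    """Models of a multi-model file (or frames of a trajectory) disagree."""


@dataclass(eq=False)
class Topology:
    """Ordered atom metadata shared by every frame of a trajectory.

    Atom order is significant and stable; (chain, residue number, atom
    name) triples must be unique.
    """

    chain_ids: tuple[str, ...]
    res_ids: tuple[int, ...]
    res_names: tuple[str, ...]
    atom_names: tuple[str, ...]
    _index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        n = len(self.chain_ids)
        if not (len(self.res_ids) == len(self.res_names) == len(self.atom_names) == n):
            raise StructureError("topology field lengths disagree")
        if n == 0:
            raise StructureError("empty topology")
        self._index = {}
        for i, key in enumerate(zip(self.chain_ids, self.res_ids, self.atom_names)):
            if key in self._index:
                raise StructureError(
                    f"duplicate atom {key[2]} in chain {key[0]} residue {key[1]}"
                )
            self._index[key] = i

    @property
    def n_atoms(self) -> int:
        return len(self.chain_ids)

    def atom_index(self, chain: str, res_id: int, atom_name: str) -> int:
        """Index of one atom; raises :class:`StructureError` if absent."""
        try:
            return self._index[(chain, res_id, atom_name)]
        except KeyError:
            raise StructureError(
                f"atom {atom_name} of chain {chain} residue {res_id} not in topology"
            ) from None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Topology):
            return NotImplemented
        return (
            self.chain_ids == other.chain_ids
            and self.res_ids == other.res_ids
            and self.res_names == other.res_names
            and self.atom_names == other.atom_names
        )

    def __hash__(self) -> int:  # content hash so topologies can key caches
        return hash((self.chain_ids, self.res_ids, self.atom_names))


@dataclass(frozen=True)
class AtomSelection:
    """Chain + inclusive residue range + atom-name class.

    ``atoms`` is ``"backbone"`` (N, CA, C, O), ``"CA"``, or an explicit
    tuple of atom names.
    """

    chain: str
    res_first: int
    res_last: int
    atoms: str | tuple[str, ...] = "backbone"

    def atom_name_set(self) -> frozenset[str]:
        if self.atoms == "backbone":
            return frozenset(BACKBONE_HEAVY)
        if self.atoms == "CA":
            return frozenset(("CA",))
        if isinstance(self.atoms, str):
            raise StructureError(f"unknown atom class {self.atoms!r}")
        return frozenset(self.atoms)


def resolve_selection(
    topology: Topology, selection: AtomSelection | Sequence[AtomSelection]
) -> np.ndarray:
    """Resolve selection(s) to atom indices in file order.

    A sequence of selections is concatenated in the order given (e.g. the
    chain-A window followed by the chain-B window for the joint clustering
    state space).  An empty result is a hard error — it almost always
    means a typo'd chain or residue range, and silently clustering on
    nothing must never happen.
    """
    if isinstance(selection, AtomSelection):
        selections = [selection]
    else:
        selections = list(selection)
    out: list[int] = []
    for sel in selections:
        names = sel.atom_name_set()
        idx = [
            i
            for i in range(topology.n_atoms)
            if topology.chain_ids[i] == sel.chain
            and sel.res_first <= topology.res_ids[i] <= sel.res_last
            and topology.atom_names[i] in names
        ]
        if not idx:
            raise StructureError(
                f"selection chain {sel.chain} residues "
                f"{sel.res_first}-{sel.res_last} ({sel.atoms}) matched no atoms"
            )
        out.extend(idx)
    return np.asarray(out, dtype=np.intp)


@dataclass
class Trajectory:
    """Ordered frames over one topology, with uniformly spaced times (ps)."""

    topology: Topology
    coords: np.ndarray  # (n_frames, n_atoms, 3), Å
    times: np.ndarray  # (n_frames,), ps
    variant: str | None = None
    replicate: int | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise StructureError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise TopologyMismatchError(
                f"coords have {self.coords.shape[1]} atoms, "
                f"topology has {self.topology.n_atoms}"
            )
        if self.times.shape != (self.coords.shape[0],):
            raise StructureError("times length must equal frame count")
        if self.n_frames >= 2:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise StructureError("frame times must be strictly increasing")
            if np.max(np.abs(dt - dt[0])) > 1e-9:
                raise StructureError("frame times must be uniformly spaced")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def frame_interval(self) -> float:
        if self.n_frames < 2:
            return 0.0
        return float(self.times[1] - self.times[0])


@dataclass(frozen=True)
class ProbePair:
    """Two Cα atom addresses whose inter-residue distance is the readout."""

    chain_a: str
    res_a: int
    chain_b: str
    res_b: int
    atom_name: str = "CA"

    def indices(self, topology: Topology) -> tuple[int, int]:
        return (
            topology.atom_index(self.chain_a, self.res_a, self.atom_name),
            topology.atom_index(self.chain_b, self.res_b, self.atom_name),
        )


@dataclass
class ReferenceStructure:
    """Single reference conformation (the crystal stand-in) and its
    probe-pair distance ``d_ref``, the normalizer for all reported
    distances."""

    topology: Topology
    coords: np.ndarray  # (n_atoms, 3), Å
    probe: ProbePair

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.shape != (self.topology.n_atoms, 3):
            raise StructureError("reference coords must have shape (n_atoms, 3)")
        if not math.isfinite(self.d_ref) or self.d_ref <= 0:
            raise StructureError("reference probe distance must be positive")

    @property
    def d_ref(self) -> float:
        ia, ib = self.probe.indices(self.topology)
        return float(np.linalg.norm(self.coords[ia] - self.coords[ib]))


# ---------------------------------------------------------------------------
# PDB text format


def _format_atom_name(name: str) -> str:
    # Standard alignment: names of <=3 characters start in column 14.
    if len(name) >= 4:
        return name[:4]
    return f" {name:<3s}"


def _atom_line(serial: int, name: str, res_name: str, chain: str, res_id: int,
               xyz: np.ndarray) -> str:
    return (
        f"ATOM  {serial:5d} {_format_atom_name(name)} {res_name:>3s} "
        f"{chain}{res_id:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
        f"          {name[0]:>2s}"
    )


def _write_model(lines: list[str], topology: Topology, coords: np.ndarray) -> None:
    for i in range(topology.n_atoms):
        lines.append(
            _atom_line(
                (i + 1) % 100000,
                topology.atom_names[i],
                topology.res_names[i],
                topology.chain_ids[i],
                topology.res_ids[i],
                coords[i],
            )
        )


def write_multimodel_pdb(trajectory: Trajectory, path: str | Path) -> None:
    """Write a trajectory as MODEL/ATOM/ENDMDL blocks (3-decimal Å) plus a
    JSON sidecar with frame interval and labels."""
    if trajectory.n_frames == 0:
        raise StructureError("refusing to write an empty trajectory")
    path = Path(path)
    lines: list[str] = []
    for f in range(trajectory.n_frames):
        lines.append(f"MODEL     {f + 1:4d}")
        _write_model(lines, trajectory.topology, trajectory.coords[f])
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    sidecar = {
        "frame_interval_ps": trajectory.frame_interval,
        "time_origin_ps": float(trajectory.times[0]),
        "variant": trajectory.variant,
        "replicate": trajectory.replicate,
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def write_reference_pdb(reference: ReferenceStructure, path: str | Path) -> None:
    """Write the reference as a single-model PDB (no MODEL records)."""
    lines: list[str] = []
    _write_model(lines, reference.topology, reference.coords)
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_atom_line(line: str, lineno: int) -> tuple[str, str, str, int, float, float, float]:
    # 1-based PDB columns: name 13-16, altLoc 17, resName 18-20, chain 22,
    # resSeq 23-26, iCode 27, x/y/z 31-54.
    try:
        name = line[12:16].strip()
        altloc = line[16].strip()
        res_name = line[17:20].strip()
        chain = line[21].strip()
        res_id = int(line[22:26])
        icode = line[26].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise PdbFormatError(f"malformed ATOM record at line {lineno}: {exc}") from None
    if altloc:
        raise PdbFormatError(f"alternate location {altloc!r} at line {lineno} not supported")
    if icode:
        raise PdbFormatError(f"insertion code {icode!r} at line {lineno} not supported")
    if not name or not chain:
        raise PdbFormatError(f"blank atom name or chain at line {lineno}")
    return name, res_name, chain, res_id, x, y, z


def _parse_models(text: str) -> list[list[tuple]]:
    models: list[list[tuple]] = []
    current: list[tuple] | None = None
    saw_model_record = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6]
        if rec == "MODEL ":
            saw_model_record = True
            if current:
                models.append(current)
            current = []
        elif rec == "ENDMDL":
            if current is not None:
                models.append(current)
            current = None
        elif rec in ("ATOM  ", "HETATM"):
            if current is None:
                if saw_model_record:
                    raise PdbFormatError(
                        f"ATOM record outside MODEL block at line {lineno}"
                    )
                current = []
            current.append(_parse_atom_line(line, lineno))
    if current:
        models.append(current)
    if not models:
        raise PdbFormatError("no ATOM records found")
    return models


def _models_to_arrays(models: list[list[tuple]], source: str) -> tuple[Topology, np.ndarray]:
    first = models[0]
    topology = Topology(
        chain_ids=tuple(a[2] for a in first),
        res_ids=tuple(a[3] for a in first),
        res_names=tuple(a[1] for a in first),
        atom_names=tuple(a[0] for a in first),
    )
    n_atoms = topology.n_atoms
    coords = np.empty((len(models), n_atoms, 3), dtype=np.float64)
    for m, model in enumerate(models):
        if len(model) != n_atoms:
            raise TopologyMismatchError(
                f"{source}: model {m + 1} has {len(model)} atoms, model 1 has {n_atoms}"
            )
        for i, atom in enumerate(model):
            if (atom[0], atom[2], atom[3]) != (
                topology.atom_names[i],
                topology.chain_ids[i],
                topology.res_ids[i],
            ):
                raise TopologyMismatchError(
                    f"{source}: model {m + 1} atom {i + 1} "
                    f"({atom[0]} {atom[2]}{atom[3]}) does not match model 1 "
                    f"({topology.atom_names[i]} {topology.chain_ids[i]}"
                    f"{topology.res_ids[i]})"
                )
            coords[m, i] = atom[4:7]
    return topology, coords


def read_multimodel_pdb(
    path: str | Path,
    frame_interval: float | None = None,
    variant: str | None = None,
    replicate: int | None = None,
) -> Trajectory:
    """Read a multi-model PDB into a :class:`Trajectory`.

    Frame metadata comes from the ``<file>.json`` sidecar when present;
    explicit keyword arguments override it.  Without either, a 10 ps
    frame interval is assumed.
    """
    path = Path(path)
    models = _parse_models(path.read_text())
    topology, coords = _models_to_arrays(models, path.name)

    sidecar_path = Path(str(path) + ".json")
    meta: dict = {}
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
    interval = frame_interval if frame_interval is not None else meta.get("frame_interval_ps")
    if interval is None or interval == 0.0:
        interval = 10.0
    origin = float(meta.get("time_origin_ps", 0.0))
    times = origin + interval * np.arange(coords.shape[0])
    return Trajectory(
        topology=topology,
        coords=coords,
        times=times,
        variant=variant if variant is not None else meta.get("variant"),
        replicate=replicate if replicate is not None else meta.get("replicate"),
    )


def read_reference_pdb(path: str | Path, probe: ProbePair) -> ReferenceStructure:
    """Read a single-model PDB as the normalizing reference structure."""
    path = Path(path)
    models = _parse_models(path.read_text())
    if len(models) != 1:
        raise StructureError(
            f"{path.name}: expected a single-model reference, found {len(models)} models"
        )
    topology, coords = _models_to_arrays(models, path.name)
    return ReferenceStructure(topology=topology, coords=coords[0], probe=probe)
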
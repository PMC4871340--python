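"""Topology and coordinate-ensemble I/O plus atom selections.

Readers are backed by MDAnalysis so multi-model PDB is first class and
XTC/DCD trajectories work behind the same contract.  Atom indices are
0-based internally; everything written to disk uses 1-based serials and
author residue numbers.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .errors import SelectionError, ValidationError

__all__ = [
    "AtomRecord",
    "AtomQuery",
    "CoordinateEnsemble",
    "State",
    "Topology",
    "default_discard",
    "load_config_mapping",
    "load_ensemble",
    "load_topology",
    "select_atoms",
    "select_union",
    "write_ensemble_pdb",
    "write_reference_pdb",
    "write_tsv",
]

_BACKBONE_NAMES = frozenset({"N", "CA", "C", "O"})


class State(str, Enum):
    """Receptor state of a run."""

    ACTIVE = "active"
    INACTIVE = "inactive"


@dataclass(frozen=True)
class AtomRecord:
    """Identity and annotations of one atom in a topology."""

    atom_index: int
    atom_name: str
    element: str
    residue_number: int
    residue_name: str
    chain_id: str
    segment_id: str
    bw_label: str | None = None

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"

    @property
    def is_calpha(self) -> bool:
        return self.atom_name == "CA" and self.is_heavy


@dataclass
class Topology:
    """Ordered atom records with residue and segment lookup tables."""

    atoms: list[AtomRecord]
    segments: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for i, a in enumerate(self.atoms):
            if a.atom_index != i:
                raise ValidationError(
                    f"atom_index must be contiguous: got {a.atom_index} at position {i}"
                )
        self.residue_atoms: dict[int, list[int]] = {}
        for a in self.atoms:
            self.residue_atoms.setdefault(a.residue_number, []).append(a.atom_index)
        ranges = sorted(self.segments.values())
        for (lo1, hi1), (lo2, _hi2) in zip(ranges, ranges[1:]):
            if lo2 <= hi1:
                raise ValidationError("segment residue ranges overlap")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def heavy_indices(self) -> np.ndarray:
        return np.array([a.atom_index for a in self.atoms if a.is_heavy], dtype=int)

    @property
    def serials(self) -> np.ndarray:
        """1-based serials for file output."""
        return np.arange(1, len(self.atoms) + 1)

    def calpha_index(self, residue_number: int) -> int:
        for i in self.residue_atoms.get(residue_number, []):
            if self.atoms[i].is_calpha:
                return i
        raise ValidationError(f"residue {residue_number} has no C-alpha atom")


@dataclass
class CoordinateEnsemble:
    """frames x atoms x 3 coordinate series (in Angstrom) for one run."""

    ligand_id: str
    state: State
    coordinates: np.ndarray
    frame_interval: float = 100.0  # ps per saved frame
    n_discarded: int = 0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValidationError("coordinates must have shape (frames, atoms, 3)")
        if self.coordinates.shape[0] < 2:
            raise ValidationError("an ensemble needs at least 2 retained frames")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValidationError("coordinates contain non-finite values")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def with_coordinates(self, coords: np.ndarray) -> "CoordinateEnsemble":
        return replace(self, coordinates=coords)


def default_discard(frame_interval: float, equilibration_ps: float = 20000.0) -> int:
    """Number of leading frames spanning the equilibration period (20 ns)."""
    if frame_interval <= 0:
        raise ValidationError("frame_interval must be positive")
    return int(np.ceil(equilibration_ps / frame_interval))


# ---------------------------------------------------------------------------
# config helpers


def load_config_mapping(source) -> dict:
    """Load a YAML/JSON mapping from a path, or pass a dict through."""
    if source is None:
        return {}
    if isinstance(source, Mapping):
        return dict(source)
    path = Path(source)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, Mapping):
        raise ValidationError(f"{path}: expected a mapping at top level")
    return dict(data)


def _guess_element(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return "X"
    if stripped[0] == "H":
        return "H"
    if len(stripped) >= 2 and stripped[:2].capitalize() in {"Cl", "Br", "Fe", "Zn", "Mg", "Na"}:
        return stripped[:2].capitalize()
    return stripped[0].upper()


def _mda_universe(*paths):
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return mda.Universe(*[str(p) for p in paths])


def load_topology(path, segment_config=None, bw_config=None) -> Topology:
    """Read a PDB topology and annotate segments and BW labels.

    ``segment_config`` maps segment_id -> [first_residue, last_residue]
    (dict or YAML/JSON path); residues not covered are grouped into
    contiguous ``loop:auto<n>`` segments.  ``bw_config`` maps residue
    number -> Ballesteros-Weinstein label string.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"topology file not found: {path}")
    try:
        u = _mda_universe(path)
    except Exception as exc:  # pragma: no cover - corrupt file path
        raise ValidationError(f"unreadable topology {path}: {exc}") from exc

    serials = getattr(u.atoms, "ids", None)
    if serials is not None and len(set(int(s) for s in serials)) != len(u.atoms):
        raise ValidationError(f"{path}: duplicate atom serials")

    try:
        elements = [str(e) for e in u.atoms.elements]
        if any(not e.strip() for e in elements):
            raise AttributeError
    except Exception:
        elements = [_guess_element(str(n)) for n in u.atoms.names]

    segments = {
        str(k): (int(v[0]), int(v[1])) for k, v in load_config_mapping(segment_config).items()
    }
    bw = {int(k): str(v) for k, v in load_config_mapping(bw_config).items()}

    resids = [int(r) for r in u.atoms.resids]
    present = set(resids)
    for seg, (lo, hi) in segments.items():
        if not any(lo <= r <= hi for r in present):
            raise ValidationError(f"segment {seg!r} range [{lo}, {hi}] matches no residue")

    def seg_of(res: int) -> str | None:
        for seg, (lo, hi) in segments.items():
            if lo <= res <= hi:
                return seg
        return None

    # contiguous runs of unassigned residues share one auto loop id
    loop_ids: dict[int, str] = {}
    counter = 0
    previous_in_loop = False
    for res in sorted(present):
        if seg_of(res) is None:
            if not previous_in_loop:
                counter += 1
            loop_ids[res] = f"loop:auto{counter}"
            previous_in_loop = True
        else:
            previous_in_loop = False

    records = []
    chain_ids = getattr(u.atoms, "chainIDs", None)
    for i, atom in enumerate(u.atoms):
        res = int(atom.resid)
        records.append(
            AtomRecord(
                atom_index=i,
                atom_name=str(atom.name),
                element=elements[i],
                residue_number=res,
                residue_name=str(atom.resname),
                chain_id=str(chain_ids[i]) if chain_ids is not None else "A",
                segment_id=seg_of(res) or loop_ids[res],
                bw_label=bw.get(res),
            )
        )
    return Topology(atoms=records, segments=segments)


def load_reference_coords(path, topology: Topology) -> np.ndarray:
    """First-model coordinates of a structure file, checked against a topology."""
    u = _mda_universe(path)
    if len(u.atoms) != topology.n_atoms:
        raise ValidationError(f"{path}: atom count does not match topology")
    return np.asarray(u.atoms.positions, dtype=np.float64)


def load_ensemble(
    path,
    topology: Topology,
    *,
    ligand_id: str,
    state: State | str,
    n_discard: int = 0,
    frame_interval: float = 100.0,
    topology_path=None,
) -> CoordinateEnsemble:
    """Read a coordinate ensemble (multi-model PDB, or XTC/DCD + topology).

    The first ``n_discard`` frames are dropped as equilibration; frame order
    is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"ensemble file not found: {path}")
    if path.suffix.lower() in {".xtc", ".dcd"}:
        if topology_path is None:
            raise ValidationError("XTC/DCD ensembles need a topology_path")
        u = _mda_universe(topology_path, path)
    else:
        u = _mda_universe(path)
    if len(u.atoms) != topology.n_atoms:
        raise ValidationError(
            f"{path}: frame atom count {len(u.atoms)} != topology atom count {topology.n_atoms}"
        )
    coords = np.array([u.atoms.positions.copy() for _ in u.trajectory], dtype=np.float64)
    if n_discard < 0:
        raise ValidationError("n_discard must be >= 0")
    if coords.shape[0] - n_discard < 2:
        raise ValidationError(
            f"{path}: fewer than 2 frames retained after discarding {n_discard}"
        )
    return CoordinateEnsemble(
        ligand_id=ligand_id,
        state=State(state),
        coordinates=coords[n_discard:],
        frame_interval=frame_interval,
        n_discarded=n_discard,
    )


# ---------------------------------------------------------------------------
# selections


@dataclass(frozen=True)
class AtomQuery:
    """Conjunctive atom selection over topology annotations.

    Fields left as ``None`` do not constrain the selection.  ``residues``
    is an explicit residue-number set, ``residue_range`` an inclusive
    [lo, hi] window; both may be combined (intersection).
    """

    heavy: bool | None = None
    calpha: bool | None = None
    backbone: bool | None = None
    residues: tuple[int, ...] | None = None
    residue_range: tuple[int, int] | None = None
    segments: tuple[str, ...] | None = None
    bw: tuple[str, ...] | None = None

    @classmethod
    def from_dict(cls, spec: Mapping) -> "AtomQuery":
        known = {
            "heavy",
            "calpha",
            "backbone",
            "residues",
            "residue_range",
            "segments",
            "bw",
        }
        unknown = set(spec) - known
        if unknown:
            raise SelectionError(f"unknown selection fields: {sorted(unknown)}")
        kwargs = dict(spec)
        for key in ("residues", "segments", "bw"):
            if kwargs.get(key) is not None:
                kwargs[key] = tuple(kwargs[key])
        if kwargs.get("residue_range") is not None:
            lo, hi = kwargs["residue_range"]
            kwargs["residue_range"] = (int(lo), int(hi))
        return cls(**kwargs)


def _matches(atom: AtomRecord, q: AtomQuery) -> bool:
    if q.heavy is not None and atom.is_heavy != q.heavy:
        return False
    if q.calpha is not None and atom.is_calpha != q.calpha:
        return False
    if q.backbone is not None and (atom.atom_name in _BACKBONE_NAMES) != q.backbone:
        return False
    if q.residues is not None and atom.residue_number not in q.residues:
        return False
    if q.residue_range is not None:
        lo, hi = q.residue_range
        if not lo <= atom.residue_number <= hi:
            return False
    if q.segments is not None and atom.segment_id not in q.segments:
        return False
    if q.bw is not None and atom.bw_label not in q.bw:
        return False
    return True


def select_atoms(topology: Topology, query: AtomQuery | Mapping) -> np.ndarray:
    """Resolve a query to a sorted array of 0-based atom indices."""
    if not isinstance(query, AtomQuery):
        query = AtomQuery.from_dict(query)
    if query.segments is not None:
        known_segments = set(topology.segments) | {a.segment_id for a in topology.atoms}
        missing = set(query.segments) - known_segments
        if missing:
            raise SelectionError(f"unknown segments: {sorted(missing)}")
    if query.residues is not None:
        missing_res = set(query.residues) - set(topology.residue_atoms)
        if missing_res:
            raise SelectionError(f"unknown residues: {sorted(missing_res)}")
    idx = [a.atom_index for a in topology.atoms if _matches(a, query)]
    return np.array(sorted(idx), dtype=int)


def select_union(topology: Topology, *queries: AtomQuery | Mapping) -> np.ndarray:
    """Union of several queries, as a sorted index array."""
    out: set[int] = set()
    for q in queries:
        out.update(select_atoms(topology, q).tolist())
    return np.array(sorted(out), dtype=int)


# ---------------------------------------------------------------------------
# writers


def _memory_universe(topology: Topology, coords: np.ndarray):
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

    n_atoms = topology.n_atoms
    residue_numbers = sorted(topology.residue_atoms)
    res_of = {r: k for k, r in enumerate(residue_numbers)}
    atom_resindex = [res_of[a.residue_number] for a in topology.atoms]
    u = mda.Universe.empty(
        n_atoms,
        n_residues=len(residue_numbers),
        atom_resindex=atom_resindex,
        residue_segindex=[0] * len(residue_numbers),
        trajectory=True,
    )
    u.add_TopologyAttr("names", [a.atom_name for a in topology.atoms])
    u.add_TopologyAttr("elements", [a.element for a in topology.atoms])
    u.add_TopologyAttr("resids", residue_numbers)
    first_atom = {r: topology.atoms[idx[0]] for r, idx in topology.residue_atoms.items()}
    u.add_TopologyAttr("resnames", [first_atom[r].residue_name for r in residue_numbers])
    u.add_TopologyAttr("chainIDs", [a.chain_id for a in topology.atoms])
    u.add_TopologyAttr("occupancies", [1.0] * n_atoms)
    u.add_TopologyAttr("tempfactors", [0.0] * n_atoms)
    u.trajectory = MemoryReader(np.asarray(coords, dtype=np.float32))
    return u


def write_ensemble_pdb(ensemble: CoordinateEnsemble, topology: Topology, path) -> None:
    """Write an ensemble as a multi-model (MODEL/ENDMDL) PDB file."""
    import MDAnalysis as mda

    if ensemble.n_atoms != topology.n_atoms:
        raise ValidationError("ensemble/topology atom count mismatch")
    u = _memory_universe(topology, ensemble.coordinates)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=topology.n_atoms, multiframe=True) as w:
            for _ in u.trajectory:
                w.write(u.atoms)


def write_reference_pdb(coords: np.ndarray, topology: Topology, path) -> None:
    """Write a single structure (atoms x 3) as a one-model PDB file."""
    import MDAnalysis as mda

    coords = np.asarray(coords, dtype=np.float64)
    if coords.shape != (topology.n_atoms, 3):
        raise ValidationError("reference coordinates must be (n_atoms, 3)")
    u = _memory_universe(topology, coords[None, :, :])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=topology.n_atoms) as w:
            w.write(u.atoms)


def write_tsv(path, header: Sequence[str], rows: Iterable[Sequence]) -> None:
    """Write rows as a TSV table with a header line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("\t".join(map(str, header)) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")
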
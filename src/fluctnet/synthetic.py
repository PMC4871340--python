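"""Synthetic toy receptors and efficacy-linked coordinate ensembles.

The generator plants a single collective mode — a latent scalar per frame
times a fixed unit displacement pattern supported on a chosen atom set —
on top of isotropic thermal noise.  The mode amplitude in the active state
is a per-ligand affine function of efficacy, while the inactive amplitude
is constant, so every downstream statistic has a closed-form ground truth:

* planted-atom RMSF = sqrt(amp^2 + 3 sigma^2)
* the planted set moves coherently, so planted pairs carry efficacy-scaled
  PCC differences while all other atoms are pure noise.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .deltas import LigandRecord, load_efficacy_table, preprocess_emax
from .errors import ValidationError
from .structure_io import (
    AtomRecord,
    CoordinateEnsemble,
    State,
    Topology,
    write_ensemble_pdb,
    write_reference_pdb,
    write_tsv,
)

__all__ = [
    "GroundTruth",
    "SyntheticPanel",
    "SyntheticPanelConfig",
    "build_toy_receptor",
    "default_coupling_pairs",
    "default_planted_atoms",
    "generate_ensemble_pair",
    "generate_panel",
    "write_panel",
]

_ATOM_NAMES = ("N", "CA", "C")
_ATOM_ELEMENTS = ("N", "C", "C")
# local offsets of N/CA/C around the residue site, twisted per residue
_OFFSETS = np.array([[0.8, 0.0, -0.5], [0.0, 0.0, 0.0], [0.0, 0.8, 0.5]])


def build_toy_receptor(
    n_residues: int,
    n_segments: int,
    *,
    bundle_radius: float = 5.0,
    rise: float = 1.5,
) -> tuple[Topology, np.ndarray]:
    """Idealized helical-bundle point cloud, three heavy atoms per residue.

    Segments are parallel columns on a circle of ``bundle_radius``;
    residues climb by ``rise`` Angstrom within each segment.  Deterministic
    for fixed arguments.
    """
    if n_segments < 2 or n_residues < n_segments:
        raise ValidationError("need n_residues >= n_segments >= 2")
    per_segment = n_residues // n_segments
    records: list[AtomRecord] = []
    coords: list[np.ndarray] = []
    segments: dict[str, tuple[int, int]] = {}
    for res in range(1, n_residues + 1):
        seg = min((res - 1) // per_segment, n_segments - 1)
        seg_id = f"H{seg + 1}"
        lo, hi = segments.get(seg_id, (res, res))
        segments[seg_id] = (min(lo, res), max(hi, res))
        theta = 2.0 * np.pi * seg / n_segments
        center = np.array([bundle_radius * np.cos(theta), bundle_radius * np.sin(theta), 0.0])
        k = (res - 1) - seg * per_segment
        twist = 0.7 * k
        rot = np.array(
            [
                [np.cos(twist), -np.sin(twist), 0.0],
                [np.sin(twist), np.cos(twist), 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        base = center + np.array([0.0, 0.0, rise * k])
        for a, name in enumerate(_ATOM_NAMES):
            records.append(
                AtomRecord(
                    atom_index=len(records),
                    atom_name=name,
                    element=_ATOM_ELEMENTS[a],
                    residue_number=res,
                    residue_name="ALA",
                    chain_id="A",
                    segment_id=seg_id,
                )
            )
            coords.append(base + rot @ _OFFSETS[a])
    return Topology(atoms=records, segments=segments), np.array(coords)


def default_planted_atoms(topology: Topology) -> tuple[int, ...]:
    """20 atoms: every atom of segment H3 plus the C-alphas of segment H4."""
    planted = []
    for a in topology.atoms:
        if a.segment_id == "H3":
            planted.append(a.atom_index)
        elif a.segment_id == "H4" and a.is_calpha:
            planted.append(a.atom_index)
    return tuple(sorted(planted))


def default_coupling_pairs(topology: Topology) -> tuple[tuple[int, int], ...]:
    """All C-alpha cross pairs between segments H3 and H4."""
    ca3 = [a.atom_index for a in topology.atoms if a.segment_id == "H3" and a.is_calpha]
    ca4 = [a.atom_index for a in topology.atoms if a.segment_id == "H4" and a.is_calpha]
    return tuple(sorted((min(i, j), max(i, j)) for i in ca3 for j in ca4))


@dataclass(frozen=True)
class SyntheticPanelConfig:
    """Knobs of the planted-mode panel generator."""

    n_residues: int = 20
    n_segments: int = 4
    efficacy_table: object = None  # path or None -> packaged panel
    efficacy_pathway: str = "gprotein"  # column that drives the planted amplitude
    planted_atoms: tuple[int, ...] | None = None  # None -> defaults on the toy receptor
    coupling_pairs: tuple[tuple[int, int], ...] | None = None
    baseline_sigma: float = 0.3
    inactive_amp: float = 0.7
    active_amp_offset: float = 1.0  # amp(E) = offset + slope * E/100, floored at 0
    active_amp_slope: float = -0.6
    n_frames: int = 1300
    frame_interval: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 100:
            raise ValidationError("n_frames must be >= 100")
        if self.baseline_sigma < 0 or self.inactive_amp < 0:
            raise ValidationError("noise amplitudes must be >= 0")
        if self.planted_atoms is not None and len(self.planted_atoms) == 0:
            raise ValidationError("planted atom set must be non-empty")

    def active_amp(self, emax: float) -> float:
        return max(0.0, self.active_amp_offset + self.active_amp_slope * emax / 100.0)

    def config_hash(self) -> str:
        payload = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
            if k != "efficacy_table"
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()


@dataclass
class GroundTruth:
    """What the generator planted, for use as a test oracle."""

    planted_atoms: tuple[int, ...]
    coupling_pairs: tuple[tuple[int, int], ...]
    ligand_ids: list[str]
    active_amps: dict[str, float]
    inactive_amp: float
    baseline_sigma: float
    seed: int
    config_hash: str
    pattern_norms: tuple[float, ...] = ()  # |p_i| per planted atom, ~1

    def expected_rmsf(self, amp: float, pattern_norm: float = 1.0) -> float:
        """Closed-form planted-atom RMSF: sqrt(amp^2 |p_i|^2 + 3 sigma^2)."""
        return float(np.sqrt((amp * pattern_norm) ** 2 + 3.0 * self.baseline_sigma**2))

    def expected_delta_rmsf(self, ligand_id: str, pattern_norm: float = 1.0) -> float:
        return self.expected_rmsf(self.active_amps[ligand_id], pattern_norm) - self.expected_rmsf(
            self.inactive_amp, pattern_norm
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "planted_atoms": list(self.planted_atoms),
                "coupling_pairs": [list(p) for p in self.coupling_pairs],
                "ligand_ids": self.ligand_ids,
                "active_amps": self.active_amps,
                "inactive_amp": self.inactive_amp,
                "baseline_sigma": self.baseline_sigma,
                "seed": self.seed,
                "config_hash": self.config_hash,
                "pattern_norms": list(self.pattern_norms),
            },
            indent=2,
            sort_keys=True,
        )


def _stream(seed: int, *key_parts) -> np.random.Generator:
    """Counter-based per-(ligand, state) stream, independent of panel order."""
    digest = hashlib.sha256("|".join(str(k) for k in key_parts).encode()).digest()
    child = int.from_bytes(digest[:8], "big")
    return np.random.default_rng(np.random.SeedSequence(entropy=(seed, child)))


def _rigid_modes(ref: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the 6 rigid-body modes of a structure (6, N, 3)."""
    n = ref.shape[0]
    centered = ref - ref.mean(axis=0)
    modes = []
    for axis in range(3):
        t = np.zeros((n, 3))
        t[:, axis] = 1.0
        modes.append(t)
    for axis in range(3):
        e = np.zeros(3)
        e[axis] = 1.0
        modes.append(np.cross(np.broadcast_to(e, (n, 3)), centered))
    flat = np.array([m.ravel() for m in modes])
    q, _ = np.linalg.qr(flat.T)
    return q.T.reshape(6, n, 3)


def _pattern(config: SyntheticPanelConfig, planted: Sequence[int], ref: np.ndarray) -> np.ndarray:
    """Fixed displacement pattern supported on the planted atoms.

    Random unit 3-vectors are projected orthogonal to the structure's
    rigid-body modes so the planted motion is purely internal and cannot
    leak into other atoms through the superposition fit.  The projection
    constraints involve only planted rows, so the support is preserved;
    row norms end up close to, but not exactly, 1 and are recorded in the
    ground truth.
    """
    rng = _stream(config.seed, "pattern")
    idx = np.asarray(planted, dtype=int)
    directions = rng.normal(size=(len(idx), 3))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    p = directions.ravel()  # planted-row block, (3k,)
    # a pattern that is zero off the planted set is orthogonal to a rigid
    # mode iff its planted block is orthogonal to the mode's planted block
    B = _rigid_modes(ref)[:, idx, :].reshape(6, -1)
    gram = B @ B.T
    p = p - B.T @ np.linalg.solve(gram, B @ p)
    block = p.reshape(len(idx), 3)
    norms = np.linalg.norm(block, axis=1)
    if np.any(norms < 1e-6):
        raise ValidationError("degenerate planted pattern; choose another seed")
    block *= np.sqrt(len(idx)) / np.linalg.norm(block)
    pattern = np.zeros((ref.shape[0], 3))
    pattern[idx] = block
    return pattern


def _simulate(
    ref: np.ndarray,
    pattern: np.ndarray,
    amp: float,
    sigma: float,
    n_frames: int,
    rng: np.random.Generator,
) -> np.ndarray:
    latent = rng.normal(scale=amp, size=n_frames) if amp > 0 else np.zeros(n_frames)
    noise = rng.normal(scale=sigma, size=(n_frames, *ref.shape)) if sigma > 0 else 0.0
    return ref[None] + noise + latent[:, None, None] * pattern[None]


def generate_ensemble_pair(
    config: SyntheticPanelConfig,
    ligand_id: str,
    emax: float,
    topology: Topology | None = None,
    ref: np.ndarray | None = None,
) -> tuple[CoordinateEnsemble, CoordinateEnsemble]:
    """Paired active/inactive ensembles for one ligand.

    Active and inactive runs differ only in the planted-mode amplitude;
    random streams are derived from the master seed and the (ligand,
    state) key, so panels are reproducible regardless of generation order.
    """
    if topology is None or ref is None:
        topology, ref = build_toy_receptor(config.n_residues, config.n_segments)
    planted = (
        config.planted_atoms
        if config.planted_atoms is not None
        else default_planted_atoms(topology)
    )
    if max(planted) >= topology.n_atoms:
        raise ValidationError("planted atom index beyond topology")
    pattern = _pattern(config, planted, ref)
    runs = {}
    for state, amp in (
        (State.ACTIVE, config.active_amp(emax)),
        (State.INACTIVE, config.inactive_amp),
    ):
        rng = _stream(config.seed, "run", ligand_id, state.value)
        coords = _simulate(ref, pattern, amp, config.baseline_sigma, config.n_frames, rng)
        runs[state] = CoordinateEnsemble(
            ligand_id=ligand_id,
            state=state,
            coordinates=coords,
            frame_interval=config.frame_interval,
        )
    return runs[State.ACTIVE], runs[State.INACTIVE]


@dataclass
class SyntheticPanel:
    """A generated panel: topology, reference, per-ligand runs, oracle."""

    topology: Topology
    reference: np.ndarray
    records: list[LigandRecord]
    efficacy: "object"  # pandas DataFrame
    ground_truth: GroundTruth
    config: SyntheticPanelConfig = field(repr=False, default=None)


def generate_panel(config: SyntheticPanelConfig) -> SyntheticPanel:
    """One ensemble pair per ligand of the efficacy table."""
    table = load_efficacy_table(config.efficacy_table)
    topology, ref = build_toy_receptor(config.n_residues, config.n_segments)
    planted = (
        config.planted_atoms
        if config.planted_atoms is not None
        else default_planted_atoms(topology)
    )
    pairs = (
        config.coupling_pairs
        if config.coupling_pairs is not None
        else default_coupling_pairs(topology)
    )
    driver_col = f"{config.efficacy_pathway}_emax_processed"
    records: list[LigandRecord] = []
    active_amps: dict[str, float] = {}
    for row in table.itertuples(index=False):
        lig = str(row.ligand_id)
        emax = float(getattr(row, driver_col))
        active, inactive = generate_ensemble_pair(config, lig, emax, topology, ref)
        records.append(
            LigandRecord(
                ligand_id=lig,
                gprotein_emax_raw=float(row.gprotein_emax),
                barrestin_emax_raw=float(row.barrestin_emax),
                active_run=active,
                inactive_run=inactive,
            )
        )
        active_amps[lig] = config.active_amp(emax)
    pattern = _pattern(config, planted, ref)
    gt = GroundTruth(
        planted_atoms=tuple(planted),
        coupling_pairs=tuple(tuple(p) for p in pairs),
        ligand_ids=[r.ligand_id for r in records],
        active_amps=active_amps,
        inactive_amp=config.inactive_amp,
        baseline_sigma=config.baseline_sigma,
        seed=config.seed,
        config_hash=config.config_hash(),
        pattern_norms=tuple(
            float(v) for v in np.linalg.norm(pattern[np.asarray(planted)], axis=1)
        ),
    )
    return SyntheticPanel(
        topology=topology,
        reference=ref,
        records=records,
        efficacy=table,
        ground_truth=gt,
        config=config,
    )


def write_panel(panel: SyntheticPanel, outdir) -> None:
    """Serialize a panel as plain-text artifacts loadable by structure_io."""
    outdir = Path(outdir)
    (outdir / "runs").mkdir(parents=True, exist_ok=True)
    write_reference_pdb(panel.reference, panel.topology, outdir / "topology.pdb")
    segments = {seg: list(rng) for seg, rng in panel.topology.segments.items()}
    (outdir / "segments.json").write_text(json.dumps(segments, indent=2, sort_keys=True))
    write_tsv(
        outdir / "efficacy.tsv",
        ("ligand_id", "gprotein_emax", "barrestin_emax"),
        (
            (r.ligand_id, r.gprotein_emax_raw, r.barrestin_emax_raw)
            for r in panel.records
        ),
    )
    for rec in panel.records:
        for run in (rec.active_run, rec.inactive_run):
            write_ensemble_pdb(
                run,
                panel.topology,
                outdir / "runs" / f"{rec.ligand_id}_{run.state.value}.pdb",
            )
    (outdir / "ground_truth.json").write_text(panel.ground_truth.to_json())
    manifest = {
        "seed": panel.config.seed,
        "config_hash": panel.config.config_hash(),
        "n_frames": panel.config.n_frames,
        "frame_interval": panel.config.frame_interval,
        "ligands": [r.ligand_id for r in panel.records],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
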
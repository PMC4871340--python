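"""Per-atom and per-pair fluctuation statistics.

All ensemble averages use denominator T (number of frames).  The scalar
pair statistic ("PCC") is the root of the sum of the nine squared
components of the 3x3 Pearson correlation submatrix between two atoms'
coordinate deviations; a ``mean`` normalization (divide the sum by 9
before the root) is available as a config switch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .structure_io import (
    AtomQuery,
    CoordinateEnsemble,
    State,
    Topology,
    select_atoms,
    write_tsv,
)

__all__ = [
    "FluctuationProfile",
    "MonitorConfig",
    "PairCorrelationMap",
    "RmsdMonitor",
    "StateMetrics",
    "compute_pair_correlation",
    "compute_rmsf",
    "compute_state_metrics",
    "mean_structure",
    "superpose_ensemble",
    "write_pair_correlation_tsv",
    "write_rmsf_tsv",
]


@dataclass
class FluctuationProfile:
    """Per-atom RMSF (Angstrom) over an ordered atom selection."""

    ligand_id: str
    state: State
    atom_indices: np.ndarray
    rmsf: np.ndarray

    def __post_init__(self) -> None:
        self.atom_indices = np.asarray(self.atom_indices, dtype=int)
        self.rmsf = np.asarray(self.rmsf, dtype=np.float64)
        if self.atom_indices.shape != self.rmsf.shape:
            raise ValidationError("atom_indices and rmsf must have equal length")
        if np.any(self.rmsf < 0):
            raise ValidationError("rmsf must be non-negative")


@dataclass
class PairCorrelationMap:
    """Per-pair 3x3 correlation submatrices and their scalar PCC."""

    ligand_id: str
    state: State
    pairs: np.ndarray  # (P, 2) atom indices
    rho: np.ndarray  # (P, 3, 3)
    pcc: np.ndarray  # (P,)
    degenerate: np.ndarray  # (P,) bool: some axis had zero variance

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=int).reshape(-1, 2)
        self.rho = np.asarray(self.rho, dtype=np.float64)
        self.pcc = np.asarray(self.pcc, dtype=np.float64)
        self.degenerate = np.asarray(self.degenerate, dtype=bool)


@dataclass(frozen=True)
class RmsdMonitor:
    """One RMSD time series: fit on ``fit_query``, measure over ``atoms_query``."""

    name: str
    atoms_query: Mapping | AtomQuery
    fit_query: Mapping | AtomQuery | None = None


@dataclass(frozen=True)
class MonitorConfig:
    """State-monitoring metrics: one C-alpha distance and RMSD series."""

    distance_pair: tuple[int, int] | None = None  # residue numbers
    rmsd_monitors: tuple[RmsdMonitor, ...] = ()


@dataclass
class StateMetrics:
    """Per-frame monitoring series for one run."""

    ligand_id: str
    state: State
    distances: np.ndarray | None = None
    rmsd: dict[str, np.ndarray] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# superposition


def _kabsch(mobile: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Proper rotation matrix R such that (mobile @ R.T) best fits ref.

    Both inputs are centered (n, 3) coordinate sets.
    """
    H = mobile.T @ ref
    U, _s, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def _fit_frames(coords: np.ndarray, ref: np.ndarray, fit_sel: np.ndarray) -> np.ndarray:
    """Rigid-fit every frame to ``ref`` using the fit selection (batched)."""
    mob = coords[:, fit_sel, :]
    mob_centroid = mob.mean(axis=1, keepdims=True)
    ref_sel = ref[fit_sel]
    ref_centroid = ref_sel.mean(axis=0)
    H = np.einsum("fni,nj->fij", mob - mob_centroid, ref_sel - ref_centroid)
    U, _s, Vt = np.linalg.svd(H)
    det = np.linalg.det(np.einsum("fij,fjk->fik", np.swapaxes(Vt, 1, 2), np.swapaxes(U, 1, 2)))
    D = np.repeat(np.eye(3)[None], coords.shape[0], axis=0)
    D[:, 2, 2] = np.sign(det)
    R = np.einsum("fij,fjk,fkl->fil", np.swapaxes(Vt, 1, 2), D, np.swapaxes(U, 1, 2))
    out = np.einsum("fni,fji->fnj", coords - mob_centroid, R) + ref_centroid
    return out


def superpose_ensemble(
    ensemble: CoordinateEnsemble,
    fit_selection: Sequence[int] | np.ndarray,
    *,
    reference: np.ndarray | None = None,
    tol: float = 1e-12,
    max_iter: int = 100,
) -> CoordinateEnsemble:
    """Remove global rigid-body motion by least-squares fitting.

    Frames are first fitted to frame 0 on the fit selection, then
    iteratively re-fitted to the ensemble-average structure until the
    average converges; the converged frames are finally expressed in the
    orientation of ``reference`` (atoms x 3) when given, else anchored at
    the input's frame 0.  The procedure is idempotent, its rotations are
    proper, and internal geometry is untouched.  Anchoring every run of a
    panel to one shared reference keeps the axis-resolved pair statistics
    comparable across runs and invariant to how the input was oriented.
    """
    fit_sel = np.asarray(fit_selection, dtype=int)
    if fit_sel.size < 3:
        raise ValidationError("fit selection needs at least 3 atoms")
    coords = ensemble.coordinates
    for frame in coords:
        pts = frame[fit_sel] - frame[fit_sel].mean(axis=0)
        if np.linalg.matrix_rank(pts, tol=1e-8) < 2:
            raise ValidationError("fit selection is collinear/degenerate in some frame")

    ref = coords[0].copy()
    for _ in range(max_iter):
        fitted = _fit_frames(coords, ref, fit_sel)
        new_ref = fitted.mean(axis=0)
        if np.max(np.abs(new_ref[fit_sel] - ref[fit_sel])) < tol:
            ref = new_ref
            break
        ref = new_ref
    fitted = _fit_frames(coords, ref, fit_sel)
    mean = fitted.mean(axis=0)
    # canonical placement: express the converged mean in the reference
    # orientation (or the frame of input frame 0) and fit frames to it
    target = np.asarray(reference, dtype=np.float64) if reference is not None else coords[0]
    if target.shape != coords[0].shape:
        raise ValidationError("reference must match the ensemble's (n_atoms, 3) shape")
    anchor = _fit_frames(mean[None], target, fit_sel)[0]
    out = _fit_frames(fitted, anchor, fit_sel)
    return ensemble.with_coordinates(out)


def mean_structure(ensemble: CoordinateEnsemble) -> np.ndarray:
    """Ensemble-average structure (atoms x 3)."""
    return ensemble.coordinates.mean(axis=0)


def compute_rmsf(
    ensemble: CoordinateEnsemble, selection: Sequence[int] | np.ndarray
) -> FluctuationProfile:
    """Per-atom root mean square fluctuation about the ensemble average.

    RMSF_i = sqrt(<dx_i^2> + <dy_i^2> + <dz_i^2>), plain means over frames.
    """
    sel = np.asarray(selection, dtype=int)
    if sel.size == 0:
        raise ValidationError("empty selection")
    dev = ensemble.coordinates[:, sel, :] - ensemble.coordinates[:, sel, :].mean(axis=0)
    rmsf = np.sqrt((dev**2).mean(axis=0).sum(axis=1))
    return FluctuationProfile(
        ligand_id=ensemble.ligand_id, state=ensemble.state, atom_indices=sel, rmsf=rmsf
    )


def compute_pair_correlation(
    ensemble: CoordinateEnsemble,
    pairs: Sequence[tuple[int, int]] | np.ndarray,
    *,
    normalization: str = "sum",
) -> PairCorrelationMap:
    """3x3 Pearson correlation submatrix and scalar PCC per atom pair.

    rho_ij^ab = <da_i db_j> / sqrt(<da_i^2><db_j^2>) for a, b in {x, y, z};
    PCC_ij is the root of the sum of the nine squared components
    (``normalization='mean'`` divides the sum by 9 first).  Components
    involving a zero-variance axis are set to 0 and the pair flagged
    degenerate.
    """
    if normalization not in {"sum", "mean"}:
        raise ValidationError("normalization must be 'sum' or 'mean'")
    pair_arr = np.asarray(pairs, dtype=int).reshape(-1, 2)
    if ensemble.n_frames < 3:
        raise ValidationError("pair correlation needs at least 3 frames")
    if pair_arr.size and (pair_arr.min() < 0 or pair_arr.max() >= ensemble.n_atoms):
        raise ValidationError("pair index out of range")

    coords = ensemble.coordinates
    dev = coords - coords.mean(axis=0)
    var = (dev**2).mean(axis=0)  # (N, 3)
    T = ensemble.n_frames

    # evaluate each pair in canonical (min, max) order so that PCC_ij and
    # PCC_ji are bit-identical; rho is transposed back for swapped inputs
    swapped = pair_arr[:, 0] > pair_arr[:, 1]
    i_idx = np.where(swapped, pair_arr[:, 1], pair_arr[:, 0])
    j_idx = np.where(swapped, pair_arr[:, 0], pair_arr[:, 1])
    cov = np.einsum("fpa,fpb->pab", dev[:, i_idx, :], dev[:, j_idx, :]) / T
    denom = np.sqrt(var[i_idx][:, :, None] * var[j_idx][:, None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), 0.0)
    degenerate = np.any(denom <= 0, axis=(1, 2))
    sq = (rho**2).sum(axis=(1, 2))
    rho[swapped] = np.swapaxes(rho[swapped], 1, 2)
    if normalization == "mean":
        sq = sq / 9.0
    pcc = np.sqrt(sq)
    return PairCorrelationMap(
        ligand_id=ensemble.ligand_id,
        state=ensemble.state,
        pairs=pair_arr,
        rho=rho,
        pcc=pcc,
        degenerate=degenerate,
    )


def compute_state_metrics(
    ensemble: CoordinateEnsemble,
    reference: np.ndarray,
    topology: Topology,
    config: MonitorConfig,
) -> StateMetrics:
    """State-monitoring series: C-alpha distance and fitted RMSD monitors."""
    metrics = StateMetrics(ligand_id=ensemble.ligand_id, state=ensemble.state)
    coords = ensemble.coordinates
    reference = np.asarray(reference, dtype=np.float64)
    if reference.shape != (topology.n_atoms, 3):
        raise ValidationError("reference must be (n_atoms, 3)")

    if config.distance_pair is not None:
        res_a, res_b = config.distance_pair
        ia, ib = topology.calpha_index(res_a), topology.calpha_index(res_b)
        metrics.distances = np.linalg.norm(coords[:, ia, :] - coords[:, ib, :], axis=-1)

    for mon in config.rmsd_monitors:
        atoms = select_atoms(topology, mon.atoms_query)
        if atoms.size == 0:
            raise ValidationError(f"monitor {mon.name!r} selects no atoms")
        fit = select_atoms(topology, mon.fit_query) if mon.fit_query is not None else atoms
        fitted = _fit_frames(coords, reference, fit)
        diff = fitted[:, atoms, :] - reference[atoms]
        metrics.rmsd[mon.name] = np.sqrt((diff**2).sum(axis=2).mean(axis=1))
    return metrics


# ---------------------------------------------------------------------------
# serialization


def write_rmsf_tsv(profile: FluctuationProfile, topology: Topology, path) -> None:
    rows = []
    for idx, value in zip(profile.atom_indices, profile.rmsf):
        a = topology.atoms[int(idx)]
        rows.append(
            (int(idx) + 1, a.residue_number, a.residue_name, a.atom_name, f"{value:.6f}")
        )
    write_tsv(path, ("serial", "residue", "resname", "atom", "rmsf"), rows)


def write_pair_correlation_tsv(pmap: PairCorrelationMap, path) -> None:
    comp_names = [f"rho_{a}{b}" for a in "xyz" for b in "xyz"]
    rows = []
    for (i, j), rho, pcc, deg in zip(pmap.pairs, pmap.rho, pmap.pcc, pmap.degenerate):
        rows.append(
            (int(i) + 1, int(j) + 1)
            + tuple(f"{v:.6f}" for v in rho.ravel())
            + (f"{pcc:.6f}", int(deg))
        )
    write_tsv(path, ("i_serial", "j_serial", *comp_names, "pcc", "degenerate"), rows)
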
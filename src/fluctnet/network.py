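"""Efficacy-correlated network extraction.

Atoms whose delta-RMSF tracks ligand efficacy across the panel beyond a
correlation threshold become "fluctuating atoms"; heavy-atom pairs with at
least one fluctuating endpoint within a distance cutoff whose delta-PCC
tracks efficacy become "couplings".  Edge-reduction rules for display are
kept separate from the analysis itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .deltas import DeltaPanel
from .errors import ValidationError
from .structure_io import Topology, write_tsv

__all__ = [
    "FluctuatingNetwork",
    "NetworkParams",
    "VisualEdge",
    "build_visual_edges",
    "enumerate_candidate_pairs",
    "panel_pearson",
    "pearson_across_panel",
    "select_couplings",
    "select_fluctuating_atoms",
    "write_edges_tcl",
    "write_network_tsvs",
]


@dataclass(frozen=True)
class NetworkParams:
    """Selection parameters for one pathway's network."""

    correlation_threshold: float = 0.6
    distance_cutoff: float = 12.0
    correlation_mode: str = "absolute"  # or "signed_positive"
    pathway: str = "gprotein"  # or "barrestin"

    def __post_init__(self) -> None:
        if not 0.0 < self.correlation_threshold:
            raise ValidationError("correlation_threshold must be positive")
        if self.distance_cutoff <= 0:
            raise ValidationError("distance_cutoff must be positive")
        if self.correlation_mode not in {"absolute", "signed_positive"}:
            raise ValidationError("correlation_mode must be 'absolute' or 'signed_positive'")
        if self.pathway not in {"gprotein", "barrestin"}:
            raise ValidationError("pathway must be 'gprotein' or 'barrestin'")

    def passes(self, r: float) -> bool:
        value = abs(r) if self.correlation_mode == "absolute" else r
        return value > self.correlation_threshold


def pearson_across_panel(values, efficacy) -> float | None:
    """Pearson product-moment r, or None when either vector has no variance."""
    x = np.asarray(values, dtype=np.float64)
    y = np.asarray(efficacy, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("values and efficacy must be 1-D and equal length")
    if x.size < 3:
        raise ValidationError("Pearson across the panel needs >= 3 ligands")
    xd, yd = x - x.mean(), y - y.mean()
    sx, sy = np.sqrt((xd**2).sum()), np.sqrt((yd**2).sum())
    if sx == 0.0 or sy == 0.0:
        return None
    return float((xd * yd).sum() / (sx * sy))


def panel_pearson(matrix: np.ndarray, efficacy) -> np.ndarray:
    """Column-wise Pearson r of a (ligands x M) matrix; NaN where undefined."""
    X = np.asarray(matrix, dtype=np.float64)
    y = np.asarray(efficacy, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValidationError("matrix rows must match efficacy length")
    if y.size < 3:
        raise ValidationError("Pearson across the panel needs >= 3 ligands")
    Xd = X - X.mean(axis=0)
    yd = y - y.mean()
    sx = np.sqrt((Xd**2).sum(axis=0))
    sy = np.sqrt((yd**2).sum())
    num = Xd.T @ yd
    out = np.full(X.shape[1], np.nan)
    if sy > 0:
        ok = sx > 0
        out[ok] = num[ok] / (sx[ok] * sy)
    return out


def select_fluctuating_atoms(
    panel: DeltaPanel,
    efficacy,
    params: NetworkParams,
    atom_subset: Sequence[int] | None = None,
) -> list[tuple[int, float]]:
    """Atoms whose delta-RMSF/efficacy correlation passes the threshold.

    Undefined correlations (zero-variance columns) are never selected.
    Output is ordered by atom index.
    """
    r = panel_pearson(panel.delta_rmsf, efficacy)
    subset = (
        set(int(a) for a in atom_subset) if atom_subset is not None else None
    )
    out = []
    for atom, rv in zip(panel.atom_indices, r):
        if subset is not None and int(atom) not in subset:
            continue
        if np.isnan(rv):
            continue
        if params.passes(float(rv)):
            out.append((int(atom), float(rv)))
    out.sort(key=lambda t: t[0])
    return out


def enumerate_candidate_pairs(
    fluctuating_atoms: Sequence[int],
    candidate_atoms: Sequence[int],
    reference_coords: np.ndarray,
    params: NetworkParams,
) -> np.ndarray:
    """All unordered pairs (i < j) with >= 1 fluctuating endpoint within cutoff.

    Distances are measured on a single reference structure so the candidate
    list is ligand independent.  Self-pairs are never produced.
    """
    fluct = np.asarray(sorted(set(int(a) for a in fluctuating_atoms)), dtype=int)
    cand = np.asarray(sorted(set(int(a) for a in candidate_atoms)), dtype=int)
    if fluct.size == 0:
        return np.zeros((0, 2), dtype=int)
    ref = np.asarray(reference_coords, dtype=np.float64)
    if ref.ndim != 2 or ref.shape[1] != 3:
        raise ValidationError("reference_coords must be (n_atoms, 3)")
    if fluct.max() >= ref.shape[0] or cand.max(initial=0) >= ref.shape[0]:
        raise ValidationError("atom index beyond reference structure")
    d = cdist(ref[fluct], ref[cand])
    pairs: set[tuple[int, int]] = set()
    for a_pos, a in enumerate(fluct):
        close = cand[d[a_pos] <= params.distance_cutoff]
        for b in close:
            if int(b) == int(a):
                continue
            pairs.add((min(int(a), int(b)), max(int(a), int(b))))
    if not pairs:
        return np.zeros((0, 2), dtype=int)
    return np.array(sorted(pairs), dtype=int)


def select_couplings(
    panel: DeltaPanel,
    efficacy,
    params: NetworkParams,
    candidate_pairs: np.ndarray,
) -> list[tuple[int, int, float]]:
    """Candidate pairs whose delta-PCC/efficacy correlation passes the threshold.

    Pairs flagged degenerate for any ligand are excluded.  Every candidate
    pair must have a column in the panel; missing columns are an error.
    """
    candidate_pairs = np.asarray(candidate_pairs, dtype=int).reshape(-1, 2)
    if candidate_pairs.shape[0] == 0:
        return []
    cols = [panel.pair_column(int(i), int(j)) for i, j in candidate_pairs]
    r = panel_pearson(panel.delta_pcc[:, cols], efficacy)
    excluded = panel.any_pair_excluded[cols]
    out = []
    for (i, j), rv, bad in zip(candidate_pairs, r, excluded):
        if bad or np.isnan(rv):
            continue
        if params.passes(float(rv)):
            out.append((int(i), int(j), float(rv)))
    out.sort(key=lambda t: (t[0], t[1]))
    return out


@dataclass
class FluctuatingNetwork:
    """Selected atoms and couplings for one pathway."""

    params: NetworkParams
    fluctuating_atoms: list[tuple[int, float]]
    couplings: list[tuple[int, int, float]]
    reference_coords: np.ndarray = field(repr=False, default=None)

    @property
    def atom_ids(self) -> set[int]:
        return {a for a, _r in self.fluctuating_atoms}

    def validate(self) -> None:
        """Re-check membership and distance invariants."""
        ids = self.atom_ids
        ref = np.asarray(self.reference_coords, dtype=np.float64)
        for _a, r in self.fluctuating_atoms:
            if not self.params.passes(r):
                raise ValidationError("fluctuating atom fails its own threshold")
        for i, j, r in self.couplings:
            if not self.params.passes(r):
                raise ValidationError("coupling fails its own threshold")
            if i not in ids and j not in ids:
                raise ValidationError("coupling without a fluctuating endpoint")
            if np.linalg.norm(ref[i] - ref[j]) > self.params.distance_cutoff + 1e-9:
                raise ValidationError("coupling beyond the distance cutoff")


@dataclass(frozen=True)
class VisualEdge:
    """One display edge after the reduction rules, with multiplicity."""

    endpoint_a: int
    endpoint_b: int
    color_class: str  # "both_fluctuating" | "one_fluctuating"
    weight: int


def build_visual_edges(network: FluctuatingNetwork, topology: Topology) -> list[VisualEdge]:
    """Reduce couplings to display edges.

    Couplings between two fluctuating atoms are kept atom-to-atom.  When
    exactly one endpoint is fluctuating, the other endpoint is replaced by
    the C-alpha of its residue and the edge is kept only if the two atoms
    lie in different segments (helix/loop).  Edges with identical endpoint
    sets and color are merged; multiplicity becomes the weight.
    """
    fluct = network.atom_ids
    counts: dict[tuple[int, int, str], int] = {}
    for i, j, _r in network.couplings:
        i_f, j_f = i in fluct, j in fluct
        if i_f and j_f:
            a, b, color = i, j, "both_fluctuating"
        else:
            kept, other = (i, j) if i_f else (j, i)
            if topology.atoms[kept].segment_id == topology.atoms[other].segment_id:
                continue
            substitute = topology.calpha_index(topology.atoms[other].residue_number)
            a, b, color = kept, substitute, "one_fluctuating"
        key = (min(a, b), max(a, b), color)
        counts[key] = counts.get(key, 0) + 1
    return [
        VisualEdge(endpoint_a=a, endpoint_b=b, color_class=color, weight=w)
        for (a, b, color), w in sorted(counts.items())
    ]


# ---------------------------------------------------------------------------
# serialization


def write_network_tsvs(network: FluctuatingNetwork, topology: Topology, outdir) -> None:
    outdir = Path(outdir)
    tag = network.params.pathway
    rows = []
    for a, r in network.fluctuating_atoms:
        atom = topology.atoms[a]
        rows.append(
            (a + 1, atom.residue_number, atom.residue_name, atom.atom_name, f"{r:.4f}")
        )
    write_tsv(
        outdir / f"fluctuating_atoms_{tag}.tsv",
        ("serial", "residue", "resname", "atom", "r"),
        rows,
    )
    ref = np.asarray(network.reference_coords, dtype=np.float64)
    write_tsv(
        outdir / f"couplings_{tag}.tsv",
        ("i_serial", "j_serial", "r", "distance"),
        (
            (i + 1, j + 1, f"{r:.4f}", f"{np.linalg.norm(ref[i] - ref[j]):.3f}")
            for i, j, r in network.couplings
        ),
    )


def write_edge_list_tsv(edges: Sequence[VisualEdge], pathway: str, outdir) -> None:
    write_tsv(
        Path(outdir) / f"visual_edges_{pathway}.tsv",
        ("a_serial", "b_serial", "color_class", "weight"),
        ((e.endpoint_a + 1, e.endpoint_b + 1, e.color_class, e.weight) for e in edges),
    )


def write_edges_tcl(
    edges: Sequence[VisualEdge],
    reference_coords: np.ndarray,
    pathway: str,
    outdir,
) -> None:
    """VMD-loadable draw script for the reduced edge list."""
    ref = np.asarray(reference_coords, dtype=np.float64)
    lines = ["# fluctuating-network edges; load in VMD with 'source'"]
    colors = {"both_fluctuating": "red", "one_fluctuating": "orange"}
    for e in edges:
        a, b = ref[e.endpoint_a], ref[e.endpoint_b]
        lines.append(f"draw color {colors[e.color_class]}")
        lines.append(
            "draw line {%.3f %.3f %.3f} {%.3f %.3f %.3f} width %d"
            % (a[0], a[1], a[2], b[0], b[1], b[2], e.weight)
        )
    Path(outdir, f"visual_edges_{pathway}.tcl").write_text("\n".join(lines) + "\n")
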
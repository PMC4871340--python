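"""Region-mean delta scores and efficacy band classification.

Scores are unweighted means of delta-RMSF over a C-alpha region and of
delta-PCC over all cross pairs between two C-alpha regions; the score
regions are fixed by configuration, independent of which atoms the
network selected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .deltas import DeltaPanel
from .errors import ValidationError
from .structure_io import AtomQuery, Topology, load_config_mapping, select_atoms

__all__ = [
    "EfficacyScore",
    "RegionDefinition",
    "classify_efficacy",
    "cross_pairs",
    "load_region_config",
    "region_mean_delta_pcc",
    "region_mean_delta_rmsf",
    "scores_frame",
]

GPROTEIN_REFERENCE_LIGAND = "ISO"
# Band edges for classification.  The beta-arrestin bands are explicit
# (>=50 strong, 10-50 moderate, <10 none); the G-protein weak band is a
# configurable lower bound whose default keeps only the inverse agonists
# and comparably inert ligands in the weak group.
BARRESTIN_STRONG = 50.0
BARRESTIN_WEAK = 10.0
GPROTEIN_WEAK_DEFAULT = 10.0


@dataclass(frozen=True)
class RegionDefinition:
    """A named C-alpha region used by the predictors."""

    name: str
    query: AtomQuery
    role: str  # "rmsf_region" | "pcc_region_a" | "pcc_region_b"

    def resolve(self, topology: Topology) -> np.ndarray:
        q = self.query
        if q.calpha is not True:
            q = AtomQuery(
                heavy=q.heavy,
                calpha=True,
                backbone=q.backbone,
                residues=q.residues,
                residue_range=q.residue_range,
                segments=q.segments,
                bw=q.bw,
            )
        atoms = select_atoms(topology, q)
        if atoms.size == 0:
            raise ValidationError(f"region {self.name!r} resolves to no atoms")
        return atoms


def load_region_config(source) -> dict[str, dict[str, RegionDefinition]]:
    """Load per-pathway region definitions from YAML/JSON or a mapping.

    Expected layout::

        gprotein:
          rmsf_region: {residue_range: [265, 286]}
          pcc_region_a: {residue_range: [265, 286]}
          pcc_region_b: {residue_range: [117, 131]}
        barrestin: ...
    """
    data = load_config_mapping(source)
    out: dict[str, dict[str, RegionDefinition]] = {}
    for pathway, regions in data.items():
        if pathway not in {"gprotein", "barrestin"}:
            continue
        if not isinstance(regions, Mapping):
            raise ValidationError(f"region config for {pathway!r} must be a mapping")
        out[pathway] = {}
        for role in ("rmsf_region", "pcc_region_a", "pcc_region_b"):
            if role not in regions:
                raise ValidationError(f"region config for {pathway!r} missing {role!r}")
            out[pathway][role] = RegionDefinition(
                name=f"{pathway}:{role}",
                query=AtomQuery.from_dict(dict(regions[role], calpha=True)),
                role=role,
            )
    if not out:
        raise ValidationError("region config defines no pathway")
    return out


def region_mean_delta_rmsf(panel: DeltaPanel, region_atoms) -> np.ndarray:
    """Per-ligand unweighted mean delta-RMSF over the region's atoms."""
    atoms = np.asarray(region_atoms, dtype=int)
    if atoms.size == 0:
        raise ValidationError("region resolves to no atoms")
    cols = [panel.atom_column(int(a)) for a in atoms]
    return panel.delta_rmsf[:, cols].mean(axis=1)


def cross_pairs(atoms_a, atoms_b) -> np.ndarray:
    """All unordered cross pairs between two regions (within-region excluded)."""
    a_set = sorted(set(int(a) for a in atoms_a))
    b_set = sorted(set(int(b) for b in atoms_b))
    pairs = {
        (min(a, b), max(a, b)) for a in a_set for b in b_set if a != b
    }
    pairs -= {
        (min(a, b), max(a, b))
        for a in a_set
        for b in a_set
        if a != b and b in set(b_set) and a in set(b_set)
    }
    if not pairs:
        raise ValidationError("regions produce no cross pairs")
    return np.array(sorted(pairs), dtype=int)


def region_mean_delta_pcc(panel: DeltaPanel, atoms_a, atoms_b) -> np.ndarray:
    """Per-ligand mean delta-PCC over all region_a x region_b cross pairs.

    Every cross pair must be present in the panel's pair order; a missing
    column is an error, never silently skipped.
    """
    pairs = cross_pairs(atoms_a, atoms_b)
    cols = [panel.pair_column(int(i), int(j)) for i, j in pairs]
    return panel.delta_pcc[:, cols].mean(axis=1)


def classify_efficacy(
    emax: Sequence[float],
    pathway: str,
    *,
    reference_emax: float | None = None,
    gprotein_weak_threshold: float = GPROTEIN_WEAK_DEFAULT,
) -> list[str]:
    """Assign strong / moderate / weak_or_none bands from preprocessed E_max.

    beta-arrestin: strong iff E >= 50, moderate iff 10 <= E < 50, else
    weak_or_none.  G protein: strong iff E >= the reference ligand's E_max
    (isoprenaline), weak_or_none iff E <= the weak threshold, else moderate.
    """
    values = np.asarray(emax, dtype=np.float64)
    labels = []
    if pathway == "barrestin":
        for v in values:
            if v >= BARRESTIN_STRONG:
                labels.append("strong")
            elif v >= BARRESTIN_WEAK:
                labels.append("moderate")
            else:
                labels.append("weak_or_none")
    elif pathway == "gprotein":
        if reference_emax is None:
            raise ValidationError("gprotein classification needs reference_emax")
        for v in values:
            if v >= reference_emax:
                labels.append("strong")
            elif v <= gprotein_weak_threshold:
                labels.append("weak_or_none")
            else:
                labels.append("moderate")
    else:
        raise ValidationError(f"unknown pathway {pathway!r}")
    return labels


@dataclass(frozen=True)
class EfficacyScore:
    ligand_id: str
    pathway: str
    mean_delta_rmsf: float
    mean_delta_pcc: float
    label: str


def scores_frame(
    panel: DeltaPanel,
    topology: Topology,
    regions: dict[str, RegionDefinition],
    efficacy: Sequence[float],
    pathway: str,
    *,
    reference_emax: float | None = None,
    gprotein_weak_threshold: float = GPROTEIN_WEAK_DEFAULT,
) -> pd.DataFrame:
    """Compute per-ligand region scores and band labels for one pathway."""
    rmsf_atoms = regions["rmsf_region"].resolve(topology)
    atoms_a = regions["pcc_region_a"].resolve(topology)
    atoms_b = regions["pcc_region_b"].resolve(topology)
    mean_rmsf = region_mean_delta_rmsf(panel, rmsf_atoms)
    mean_pcc = region_mean_delta_pcc(panel, atoms_a, atoms_b)
    labels = classify_efficacy(
        efficacy,
        pathway,
        reference_emax=reference_emax,
        gprotein_weak_threshold=gprotein_weak_threshold,
    )
    return pd.DataFrame(
        {
            "ligand_id": panel.ligand_ids,
            "pathway": pathway,
            "mean_delta_rmsf": mean_rmsf,
            "mean_delta_pcc": mean_pcc,
            "emax": np.asarray(efficacy, dtype=np.float64),
            "efficacy_class": labels,
        }
    )
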
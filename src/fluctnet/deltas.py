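"""Active-minus-inactive differences, assembled across a ligand panel."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .fluctuation import FluctuationProfile, PairCorrelationMap
from .structure_io import write_tsv

__all__ = [
    "DeltaPanel",
    "LigandRecord",
    "assemble_panel",
    "delta_pcc",
    "delta_rmsf",
    "load_efficacy_table",
    "preprocess_emax",
    "write_panel_tsvs",
]

MIN_PANEL_SIZE = 3  # Pearson across the panel is undefined below this


def preprocess_emax(values) -> np.ndarray:
    """Clip raw E_max percentages to [0, 100]; values above 100 are treated as 100."""
    arr = np.asarray(values, dtype=np.float64)
    if np.any(arr < 0) or not np.all(np.isfinite(arr)):
        raise ValidationError("raw E_max values must be finite and >= 0")
    return np.minimum(arr, 100.0)


def load_efficacy_table(path=None) -> pd.DataFrame:
    """Load a ligand efficacy table (TSV) and add preprocessed columns.

    With no path, the packaged 14-ligand reference panel is used.  The
    table needs columns ``ligand_id``, ``gprotein_emax``, ``barrestin_emax``
    (raw %); processed columns get a ``_processed`` suffix.
    """
    if path is None:
        source = resources.files("fluctnet.data") / "ligand_efficacy.tsv"
        with resources.as_file(source) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        path = Path(path)
        if not path.exists():
            raise ValidationError(f"efficacy table not found: {path}")
        df = pd.read_csv(path, sep="\t")
    required = {"ligand_id", "gprotein_emax", "barrestin_emax"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"efficacy table missing columns: {sorted(missing)}")
    if df["ligand_id"].duplicated().any():
        raise ValidationError("duplicate ligand_id in efficacy table")
    for col in ("gprotein_emax", "barrestin_emax"):
        df[f"{col}_processed"] = preprocess_emax(df[col].to_numpy())
    return df


@dataclass
class LigandRecord:
    """One ligand of the panel with its preprocessed efficacies."""

    ligand_id: str
    gprotein_emax_raw: float
    barrestin_emax_raw: float
    active_run: object = None  # CoordinateEnsemble or a path reference
    inactive_run: object = None

    @property
    def gprotein_emax(self) -> float:
        return float(preprocess_emax([self.gprotein_emax_raw])[0])

    @property
    def barrestin_emax(self) -> float:
        return float(preprocess_emax([self.barrestin_emax_raw])[0])


def delta_rmsf(active: FluctuationProfile, inactive: FluctuationProfile) -> np.ndarray:
    """Per-atom RMSF difference, active minus inactive (may be negative)."""
    if active.atom_indices.shape != inactive.atom_indices.shape or np.any(
        active.atom_indices != inactive.atom_indices
    ):
        raise ValidationError("profiles cover different atom sets; refusing to intersect")
    return active.rmsf - inactive.rmsf


def delta_pcc(
    active: PairCorrelationMap, inactive: PairCorrelationMap
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pair PCC difference and an exclusion mask.

    Pairs degenerate in either state are flagged in the returned mask and
    must be excluded from downstream correlation screens; their delta
    value is set to 0 as a placeholder, never interpreted.
    """
    if active.pairs.shape != inactive.pairs.shape or np.any(active.pairs != inactive.pairs):
        raise ValidationError("pair lists differ between states")
    excluded = active.degenerate | inactive.degenerate
    delta = np.where(excluded, 0.0, active.pcc - inactive.pcc)
    return delta, excluded


@dataclass
class DeltaPanel:
    """Panel-wide ligands x atoms and ligands x pairs delta matrices."""

    ligand_ids: list[str]
    atom_indices: np.ndarray  # (A,)
    delta_rmsf: np.ndarray  # (L, A)
    pair_list: np.ndarray  # (P, 2)
    delta_pcc: np.ndarray  # (L, P)
    pair_excluded: np.ndarray  # (L, P) bool

    def __post_init__(self) -> None:
        self.atom_indices = np.asarray(self.atom_indices, dtype=int)
        self.delta_rmsf = np.asarray(self.delta_rmsf, dtype=np.float64)
        self.pair_list = np.asarray(self.pair_list, dtype=int).reshape(-1, 2)
        self.delta_pcc = np.asarray(self.delta_pcc, dtype=np.float64)
        self.pair_excluded = np.asarray(self.pair_excluded, dtype=bool)
        L = len(self.ligand_ids)
        if self.delta_rmsf.shape != (L, self.atom_indices.size):
            raise ValidationError("delta_rmsf shape does not match ligand/atom orders")
        if self.delta_pcc.shape != (L, self.pair_list.shape[0]):
            raise ValidationError("delta_pcc shape does not match ligand/pair orders")
        if self.pair_excluded.shape != self.delta_pcc.shape:
            raise ValidationError("pair_excluded shape mismatch")
        if not np.all(np.isfinite(self.delta_rmsf)) or not np.all(np.isfinite(self.delta_pcc)):
            raise ValidationError("panel matrices must be finite")

    @property
    def n_ligands(self) -> int:
        return len(self.ligand_ids)

    @property
    def any_pair_excluded(self) -> np.ndarray:
        """Pairs excluded for at least one ligand (unusable for panel screens)."""
        return self.pair_excluded.any(axis=0)

    def atom_column(self, atom_index: int) -> int:
        hits = np.nonzero(self.atom_indices == atom_index)[0]
        if hits.size != 1:
            raise ValidationError(f"atom {atom_index} not in panel atom order")
        return int(hits[0])

    def pair_column(self, i: int, j: int) -> int:
        a, b = min(i, j), max(i, j)
        hits = np.nonzero((self.pair_list[:, 0] == a) & (self.pair_list[:, 1] == b))[0]
        if hits.size != 1:
            raise ValidationError(f"pair ({i}, {j}) not in panel pair order")
        return int(hits[0])


def assemble_panel(
    ligand_ids: Sequence[str],
    atom_indices,
    rmsf_deltas: Sequence[np.ndarray],
    pair_list,
    pcc_deltas: Sequence[np.ndarray],
    pcc_excluded: Sequence[np.ndarray],
) -> DeltaPanel:
    """Stack per-ligand delta vectors into panel matrices in declared order."""
    if len(ligand_ids) < MIN_PANEL_SIZE:
        raise ValidationError(
            f"panel needs >= {MIN_PANEL_SIZE} ligands, got {len(ligand_ids)}"
        )
    if len(set(ligand_ids)) != len(ligand_ids):
        raise ValidationError("duplicate ligand ids in panel")
    if not (len(rmsf_deltas) == len(pcc_deltas) == len(pcc_excluded) == len(ligand_ids)):
        raise ValidationError("per-ligand delta lists must match the ligand order")
    atom_indices = np.asarray(atom_indices, dtype=int)
    pair_list = np.asarray(pair_list, dtype=int).reshape(-1, 2)
    for v in rmsf_deltas:
        if np.asarray(v).shape != (atom_indices.size,):
            raise ValidationError("a ligand's delta RMSF does not share the atom order")
    for v in pcc_deltas:
        if np.asarray(v).shape != (pair_list.shape[0],):
            raise ValidationError("a ligand's delta PCC does not share the pair order")
    return DeltaPanel(
        ligand_ids=list(ligand_ids),
        atom_indices=atom_indices,
        delta_rmsf=np.vstack([np.asarray(v, dtype=np.float64) for v in rmsf_deltas])
        if rmsf_deltas
        else np.zeros((0, 0)),
        pair_list=pair_list,
        delta_pcc=np.vstack([np.asarray(v, dtype=np.float64) for v in pcc_deltas]),
        pair_excluded=np.vstack([np.asarray(v, dtype=bool) for v in pcc_excluded]),
    )


def write_panel_tsvs(panel: DeltaPanel, outdir) -> None:
    """Serialize a panel to atom/pair TSVs plus a JSON order manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    atom_cols = [str(int(i) + 1) for i in panel.atom_indices]
    write_tsv(
        outdir / "delta_rmsf.tsv",
        ["ligand_id", *atom_cols],
        (
            [lig, *(f"{v:.6f}" for v in row)]
            for lig, row in zip(panel.ligand_ids, panel.delta_rmsf)
        ),
    )
    pair_cols = [f"{int(i) + 1}-{int(j) + 1}" for i, j in panel.pair_list]
    write_tsv(
        outdir / "delta_pcc.tsv",
        ["ligand_id", *pair_cols],
        (
            [lig, *(f"{v:.6f}" for v in row)]
            for lig, row in zip(panel.ligand_ids, panel.delta_pcc)
        ),
    )
    manifest = {
        "ligand_order": panel.ligand_ids,
        "atom_serials": [int(i) + 1 for i in panel.atom_indices],
        "pair_serials": [[int(i) + 1, int(j) + 1] for i, j in panel.pair_list],
        "excluded_pairs": [
            [int(i) + 1, int(j) + 1]
            for (i, j), bad in zip(panel.pair_list, panel.any_pair_excluded)
            if bad
        ],
    }
    manifest["sha256"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()
    ).hexdigest()
    (outdir / "panel_manifest.json").write_text(json.dumps(manifest, indent=2))


def read_panel_tsvs(outdir) -> DeltaPanel:
    """Inverse of :func:`write_panel_tsvs` (exclusion collapses to per-panel)."""
    outdir = Path(outdir)
    rmsf_df = pd.read_csv(outdir / "delta_rmsf.tsv", sep="\t")
    pcc_df = pd.read_csv(outdir / "delta_pcc.tsv", sep="\t")
    manifest = json.loads((outdir / "panel_manifest.json").read_text())
    ligand_ids = [str(v) for v in rmsf_df["ligand_id"]]
    atom_indices = np.array([int(c) - 1 for c in rmsf_df.columns[1:]], dtype=int)
    pair_list = np.array(
        [[int(p) - 1 for p in c.split("-")] for c in pcc_df.columns[1:]], dtype=int
    )
    excluded_serials = {tuple(p) for p in manifest.get("excluded_pairs", [])}
    excluded_row = np.array(
        [(int(i) + 1, int(j) + 1) in excluded_serials for i, j in pair_list], dtype=bool
    )
    return DeltaPanel(
        ligand_ids=ligand_ids,
        atom_indices=atom_indices,
        delta_rmsf=rmsf_df.iloc[:, 1:].to_numpy(dtype=np.float64),
        pair_list=pair_list,
        delta_pcc=pcc_df.iloc[:, 1:].to_numpy(dtype=np.float64),
        pair_excluded=np.tile(excluded_row, (len(ligand_ids), 1)),
    )
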
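"""End-to-end orchestration: load -> superpose -> RMSF/PCC -> deltas ->
network per pathway -> region scores.

The in-memory entry point :func:`analyze_records` is the single code path
used by the CLI, the tests, and the acceptance script; file-based stages
wrap it around a panel directory produced by ``fluctnet synth`` (or laid
out the same way for real trajectories).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .deltas import (
    DeltaPanel,
    LigandRecord,
    assemble_panel,
    delta_pcc,
    delta_rmsf,
    load_efficacy_table,
    write_panel_tsvs,
)
from .errors import ValidationError
from .fluctuation import (
    compute_pair_correlation,
    compute_rmsf,
    mean_structure,
    superpose_ensemble,
    write_rmsf_tsv,
)
from .network import (
    FluctuatingNetwork,
    NetworkParams,
    build_visual_edges,
    enumerate_candidate_pairs,
    select_couplings,
    select_fluctuating_atoms,
    write_edge_list_tsv,
    write_edges_tcl,
    write_network_tsvs,
)
from .prediction import (
    GPROTEIN_REFERENCE_LIGAND,
    GPROTEIN_WEAK_DEFAULT,
    RegionDefinition,
    cross_pairs,
    load_region_config,
    scores_frame,
)
from .structure_io import (
    AtomQuery,
    State,
    Topology,
    load_ensemble,
    load_reference_coords,
    load_topology,
    select_atoms,
    write_reference_pdb,
)

PATHWAYS = ("gprotein", "barrestin")


def toy_region_config() -> dict:
    """Score regions for the synthetic toy receptor (planted segments)."""
    regions = {
        "rmsf_region": {"segments": ["H3"]},
        "pcc_region_a": {"segments": ["H3"]},
        "pcc_region_b": {"segments": ["H4"]},
    }
    return {"gprotein": regions, "barrestin": regions}


@dataclass(frozen=True)
class PipelineConfig:
    """Validated configuration for one pipeline invocation."""

    panel_dir: Path
    out_dir: Path
    correlation_threshold: float = 0.6
    distance_cutoff: float = 12.0
    correlation_mode: str = "absolute"
    pcc_normalization: str = "sum"
    n_discard: int = 0
    pathways: tuple[str, ...] = PATHWAYS
    region_config: object = None  # path/mapping; None -> toy defaults
    gprotein_weak_threshold: float = GPROTEIN_WEAK_DEFAULT
    gprotein_reference_emax: float | None = None  # None -> reference ligand's value

    def validate(self) -> None:
        if not Path(self.panel_dir).is_dir():
            raise ValidationError(f"panel directory not found: {self.panel_dir}")
        for name in ("topology.pdb", "efficacy.tsv"):
            if not (Path(self.panel_dir) / name).exists():
                raise ValidationError(f"panel directory missing {name}")
        if not (Path(self.panel_dir) / "runs").is_dir():
            raise ValidationError("panel directory missing runs/")
        unknown = set(self.pathways) - set(PATHWAYS)
        if unknown:
            raise ValidationError(f"unknown pathways: {sorted(unknown)}")
        NetworkParams(
            correlation_threshold=self.correlation_threshold,
            distance_cutoff=self.distance_cutoff,
            correlation_mode=self.correlation_mode,
        )

    def config_hash(self) -> str:
        payload = {
            "threshold": self.correlation_threshold,
            "cutoff": self.distance_cutoff,
            "mode": self.correlation_mode,
            "normalization": self.pcc_normalization,
            "n_discard": self.n_discard,
            "pathways": list(self.pathways),
            "gprotein_weak_threshold": self.gprotein_weak_threshold,
            "version": __version__,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


@dataclass
class AnalysisResult:
    """Everything the pipeline computes for one panel."""

    topology: Topology
    reference: np.ndarray
    panel: DeltaPanel
    efficacy: pd.DataFrame
    networks: dict[str, FluctuatingNetwork] = field(default_factory=dict)
    edges: dict[str, list] = field(default_factory=dict)
    scores: dict[str, pd.DataFrame] = field(default_factory=dict)
    profiles: dict[tuple[str, str], object] = field(default_factory=dict)


def default_fit_selection(topology: Topology) -> np.ndarray:
    """Backbone heavy atoms; falls back to all heavy atoms."""
    sel = select_atoms(topology, AtomQuery(heavy=True, backbone=True))
    return sel if sel.size >= 3 else topology.heavy_indices


def analyze_records(
    topology: Topology,
    records: Sequence[LigandRecord],
    efficacy: pd.DataFrame,
    *,
    correlation_threshold: float = 0.6,
    distance_cutoff: float = 12.0,
    correlation_mode: str = "absolute",
    pcc_normalization: str = "sum",
    pathways: Sequence[str] = PATHWAYS,
    regions: Mapping[str, Mapping[str, RegionDefinition]] | None = None,
    gprotein_weak_threshold: float = GPROTEIN_WEAK_DEFAULT,
    gprotein_reference_emax: float | None = None,
    fit_reference: np.ndarray | None = None,
) -> AnalysisResult:
    """Run the full analysis on in-memory paired ensembles.

    ``records`` must carry ``active_run``/``inactive_run`` ensembles; the
    efficacy table provides the preprocessed per-pathway E_max columns.
    """
    if len(records) < 3:
        raise ValidationError("analysis needs at least 3 ligands")
    order = {str(r): k for k, r in enumerate(efficacy["ligand_id"])}
    missing = [r.ligand_id for r in records if r.ligand_id not in order]
    if missing:
        raise ValidationError(f"ligands without efficacy entries: {missing}")

    heavy = topology.heavy_indices
    fit_sel = default_fit_selection(topology)

    superposed: dict[tuple[str, State], object] = {}
    profiles: dict[tuple[str, str], object] = {}
    inactive_means = []
    for rec in records:
        for run in (rec.active_run, rec.inactive_run):
            if run is None:
                raise ValidationError(f"ligand {rec.ligand_id} is missing a run")
            fitted = superpose_ensemble(run, fit_sel, reference=fit_reference)
            superposed[(rec.ligand_id, run.state)] = fitted
            profiles[(rec.ligand_id, run.state.value)] = compute_rmsf(fitted, heavy)
            if run.state is State.INACTIVE:
                inactive_means.append(mean_structure(fitted))
    # ligand-independent reference for the distance cutoff: the panel
    # average of inactive-state mean structures
    reference = np.mean(inactive_means, axis=0)

    rmsf_deltas = [
        delta_rmsf(profiles[(r.ligand_id, "active")], profiles[(r.ligand_id, "inactive")])
        for r in records
    ]
    delta_rmsf_matrix = np.vstack(rmsf_deltas)

    efficacy_vectors = {}
    for pathway in pathways:
        col = f"{pathway}_emax_processed"
        efficacy_vectors[pathway] = np.array(
            [efficacy[col].to_numpy()[order[r.ligand_id]] for r in records]
        )

    # atom screen needs only delta RMSF: use a pairless panel
    atom_panel = DeltaPanel(
        ligand_ids=[r.ligand_id for r in records],
        atom_indices=heavy,
        delta_rmsf=delta_rmsf_matrix,
        pair_list=np.zeros((0, 2), dtype=int),
        delta_pcc=np.zeros((len(records), 0)),
        pair_excluded=np.zeros((len(records), 0), dtype=bool),
    )

    params_by_pathway = {
        pathway: NetworkParams(
            correlation_threshold=correlation_threshold,
            distance_cutoff=distance_cutoff,
            correlation_mode=correlation_mode,
            pathway=pathway,
        )
        for pathway in pathways
    }
    fluct_by_pathway = {
        pathway: select_fluctuating_atoms(
            atom_panel, efficacy_vectors[pathway], params_by_pathway[pathway]
        )
        for pathway in pathways
    }
    candidates_by_pathway = {
        pathway: enumerate_candidate_pairs(
            [a for a, _ in fluct_by_pathway[pathway]],
            heavy,
            reference,
            params_by_pathway[pathway],
        )
        for pathway in pathways
    }

    if regions is None:
        regions = {}
    region_pairs: dict[str, np.ndarray] = {}
    for pathway, defs in regions.items():
        region_pairs[pathway] = cross_pairs(
            defs["pcc_region_a"].resolve(topology), defs["pcc_region_b"].resolve(topology)
        )

    all_pairs: set[tuple[int, int]] = set()
    for arr in list(candidates_by_pathway.values()) + list(region_pairs.values()):
        all_pairs.update((int(i), int(j)) for i, j in arr)
    pair_list = np.array(sorted(all_pairs), dtype=int) if all_pairs else np.zeros((0, 2), int)

    pcc_deltas, pcc_excluded = [], []
    for rec in records:
        pcc_active = compute_pair_correlation(
            superposed[(rec.ligand_id, State.ACTIVE)], pair_list,
            normalization=pcc_normalization,
        )
        pcc_inactive = compute_pair_correlation(
            superposed[(rec.ligand_id, State.INACTIVE)], pair_list,
            normalization=pcc_normalization,
        )
        d, excl = delta_pcc(pcc_active, pcc_inactive)
        pcc_deltas.append(d)
        pcc_excluded.append(excl)

    panel = assemble_panel(
        [r.ligand_id for r in records], heavy, rmsf_deltas, pair_list, pcc_deltas, pcc_excluded
    )

    result = AnalysisResult(
        topology=topology,
        reference=reference,
        panel=panel,
        efficacy=efficacy,
        profiles=profiles,
    )
    for pathway in pathways:
        params = params_by_pathway[pathway]
        couplings = select_couplings(
            panel, efficacy_vectors[pathway], params, candidates_by_pathway[pathway]
        )
        net = FluctuatingNetwork(
            params=params,
            fluctuating_atoms=fluct_by_pathway[pathway],
            couplings=couplings,
            reference_coords=reference,
        )
        result.networks[pathway] = net
        result.edges[pathway] = build_visual_edges(net, topology)
        if pathway in regions:
            ref_emax = None
            if pathway == "gprotein":
                ref_emax = gprotein_reference_emax
                if ref_emax is None:
                    ref_rows = efficacy[efficacy["ligand_id"] == GPROTEIN_REFERENCE_LIGAND]
                    if ref_rows.empty:
                        raise ValidationError(
                            f"reference ligand {GPROTEIN_REFERENCE_LIGAND!r} missing from "
                            "table and no explicit reference E_max given"
                        )
                    ref_emax = float(ref_rows["gprotein_emax_processed"].iloc[0])
            result.scores[pathway] = scores_frame(
                panel,
                topology,
                regions[pathway],
                efficacy_vectors[pathway],
                pathway,
                reference_emax=ref_emax,
                gprotein_weak_threshold=gprotein_weak_threshold,
            )
    return result


# ---------------------------------------------------------------------------
# file-based stages


def load_panel_dir(config: PipelineConfig):
    """Load topology, runs, and efficacy from a panel directory."""
    config.validate()
    panel_dir = Path(config.panel_dir)
    seg_path = None
    for candidate in ("segments.json", "segments.yaml"):
        if (panel_dir / candidate).exists():
            seg_path = panel_dir / candidate
            break
    topology = load_topology(panel_dir / "topology.pdb", segment_config=seg_path)
    efficacy = load_efficacy_table(panel_dir / "efficacy.tsv")
    frame_interval = 100.0
    manifest_path = panel_dir / "manifest.json"
    if manifest_path.exists():
        frame_interval = float(
            json.loads(manifest_path.read_text()).get("frame_interval", 100.0)
        )
    records = []
    for row in efficacy.itertuples(index=False):
        lig = str(row.ligand_id)
        runs = {}
        for state in (State.ACTIVE, State.INACTIVE):
            path = panel_dir / "runs" / f"{lig}_{state.value}.pdb"
            if not path.exists():
                raise ValidationError(f"missing run file: {path}")
            runs[state] = load_ensemble(
                path,
                topology,
                ligand_id=lig,
                state=state,
                n_discard=config.n_discard,
                frame_interval=frame_interval,
            )
        records.append(
            LigandRecord(
                ligand_id=lig,
                gprotein_emax_raw=float(row.gprotein_emax),
                barrestin_emax_raw=float(row.barrestin_emax),
                active_run=runs[State.ACTIVE],
                inactive_run=runs[State.INACTIVE],
            )
        )
    ref_coords = load_reference_coords(panel_dir / "topology.pdb", topology)
    return topology, records, efficacy, ref_coords


def _resolve_regions(config: PipelineConfig):
    source = config.region_config
    if source is None:
        for candidate in ("regions.yaml", "regions.json"):
            path = Path(config.panel_dir) / candidate
            if path.exists():
                source = path
                break
    if source is None:
        source = toy_region_config()
    data = source
    if not isinstance(source, Mapping):
        data = source  # path; load_region_config handles it
    else:
        data = dict(source)
    if isinstance(data, Mapping) and "regions" in data:
        data = data["regions"]
    return load_region_config(data)


def _analyze_config(config: PipelineConfig) -> AnalysisResult:
    topology, records, efficacy, ref_coords = load_panel_dir(config)
    return analyze_records(
        topology,
        records,
        efficacy,
        correlation_threshold=config.correlation_threshold,
        distance_cutoff=config.distance_cutoff,
        correlation_mode=config.correlation_mode,
        pcc_normalization=config.pcc_normalization,
        pathways=config.pathways,
        regions=_resolve_regions(config),
        gprotein_weak_threshold=config.gprotein_weak_threshold,
        gprotein_reference_emax=config.gprotein_reference_emax,
        fit_reference=ref_coords,
    )


def _write_manifest(config: PipelineConfig, out: Path, stage: str) -> None:
    manifest = {
        "stage": stage,
        "config_hash": config.config_hash(),
        "version": __version__,
        "panel_dir": str(config.panel_dir),
    }
    (out / f"{stage}_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def run_fluct_stage(config: PipelineConfig) -> None:
    """Superpose every run and write per-run RMSF tables plus the reference."""
    topology, records, _efficacy, ref_coords = load_panel_dir(config)
    out = Path(config.out_dir)
    (out / "rmsf").mkdir(parents=True, exist_ok=True)
    heavy = topology.heavy_indices
    fit_sel = default_fit_selection(topology)
    inactive_means = []
    for rec in records:
        for run in (rec.active_run, rec.inactive_run):
            fitted = superpose_ensemble(run, fit_sel, reference=ref_coords)
            profile = compute_rmsf(fitted, heavy)
            write_rmsf_tsv(
                profile, topology, out / "rmsf" / f"{rec.ligand_id}_{run.state.value}.tsv"
            )
            if run.state is State.INACTIVE:
                inactive_means.append(mean_structure(fitted))
    write_reference_pdb(np.mean(inactive_means, axis=0), topology, out / "reference.pdb")
    _write_manifest(config, out, "fluct")


def run_delta_stage(config: PipelineConfig) -> None:
    """Write the ligands x atoms delta-RMSF matrix (pair deltas are computed
    by the network stage, which knows the candidate pair list)."""
    topology, records, _efficacy, ref_coords = load_panel_dir(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    heavy = topology.heavy_indices
    fit_sel = default_fit_selection(topology)
    rmsf_deltas = []
    for rec in records:
        prof = {}
        for run in (rec.active_run, rec.inactive_run):
            prof[run.state] = compute_rmsf(
                superpose_ensemble(run, fit_sel, reference=ref_coords), heavy
            )
        rmsf_deltas.append(delta_rmsf(prof[State.ACTIVE], prof[State.INACTIVE]))
    panel = DeltaPanel(
        ligand_ids=[r.ligand_id for r in records],
        atom_indices=heavy,
        delta_rmsf=np.vstack(rmsf_deltas),
        pair_list=np.zeros((0, 2), dtype=int),
        delta_pcc=np.zeros((len(records), 0)),
        pair_excluded=np.zeros((len(records), 0), dtype=bool),
    )
    write_panel_tsvs(panel, out)
    _write_manifest(config, out, "delta")


def run_network_stage(config: PipelineConfig) -> AnalysisResult:
    """Select fluctuating atoms and couplings and write network artifacts."""
    topology, records, efficacy, ref_coords = load_panel_dir(config)
    result = analyze_records(
        topology,
        records,
        efficacy,
        correlation_threshold=config.correlation_threshold,
        distance_cutoff=config.distance_cutoff,
        correlation_mode=config.correlation_mode,
        pcc_normalization=config.pcc_normalization,
        pathways=config.pathways,
        regions={},
        fit_reference=ref_coords,
    )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_panel_tsvs(result.panel, out)
    for pathway, net in result.networks.items():
        write_network_tsvs(net, result.topology, out)
        write_edge_list_tsv(result.edges[pathway], pathway, out)
        write_edges_tcl(result.edges[pathway], result.reference, pathway, out)
    _write_manifest(config, out, "network")
    return result


def run_predict_stage(config: PipelineConfig) -> AnalysisResult:
    """Compute region-mean scores and band labels and write scores.tsv."""
    topology, records, efficacy, ref_coords = load_panel_dir(config)
    result = analyze_records(
        topology,
        records,
        efficacy,
        correlation_threshold=config.correlation_threshold,
        distance_cutoff=config.distance_cutoff,
        correlation_mode=config.correlation_mode,
        pcc_normalization=config.pcc_normalization,
        pathways=config.pathways,
        regions=_resolve_regions(config),
        gprotein_weak_threshold=config.gprotein_weak_threshold,
        gprotein_reference_emax=config.gprotein_reference_emax,
        fit_reference=ref_coords,
    )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.concat(result.scores.values(), ignore_index=True).to_csv(
        out / "scores.tsv", sep="\t", index=False, float_format="%.6f"
    )
    _write_manifest(config, out, "predict")
    return result


def run_pipeline(config: PipelineConfig) -> AnalysisResult:
    """Execute every stage and write all artifacts to ``config.out_dir``."""
    result = _analyze_config(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rmsf_dir = out / "rmsf"
    rmsf_dir.mkdir(exist_ok=True)
    for (lig, state), profile in result.profiles.items():
        write_rmsf_tsv(profile, result.topology, rmsf_dir / f"{lig}_{state}.tsv")
    write_reference_pdb(result.reference, result.topology, out / "reference.pdb")
    write_panel_tsvs(result.panel, out)
    for pathway, net in result.networks.items():
        write_network_tsvs(net, result.topology, out)
        write_edge_list_tsv(result.edges[pathway], pathway, out)
        write_edges_tcl(result.edges[pathway], result.reference, pathway, out)
    if result.scores:
        pd.concat(result.scores.values(), ignore_index=True).to_csv(
            out / "scores.tsv", sep="\t", index=False, float_format="%.6f"
        )
    _write_manifest(config, out, "analyze")
    return result
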
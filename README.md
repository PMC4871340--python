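# fluctnet

Fluctuating-network analysis of paired active/inactive receptor ensembles.

Given coordinate ensembles of a receptor simulated in its active and
inactive states while bound to a panel of ligands with known pathway
efficacies (E_max for a G-protein and a β-arrestin readout), `fluctnet`:

1. superposes each run and computes per-atom **RMSF** and, per atom pair,
   the 3×3 Pearson correlation submatrix of coordinate deviations reduced
   to a scalar **PCC** (root of the sum of the nine squared components);
2. forms per-ligand active-minus-inactive differences (**ΔRMSF**, **ΔPCC**);
3. correlates those differences with efficacy across the ligand panel and
   extracts the **fluctuating network**: heavy atoms with |r| above a
   threshold (default 0.6) and atom–atom couplings (≥ 1 fluctuating
   endpoint, within 12 Å on a reference structure) whose ΔPCC passes the
   same screen — independently for the G-protein and β-arrestin pathways;
4. reduces couplings to a display edge list (Cα substitution, different-
   segment rule, line-width weights) exportable as TSV and a VMD Tcl script;
5. computes region-mean ΔRMSF/ΔPCC scores over configurable Cα regions and
   classifies ligands into strong / moderate / weak-or-none efficacy bands.

Because no trajectories of the original study are deposited, the package
ships a **synthetic generator**: toy helical-bundle receptors with a
planted, efficacy-scaled internal collective mode on top of isotropic
thermal noise, giving closed-form ground truth for every downstream
statistic. A 14-ligand efficacy table and β2AR region/BW-label fixtures
are packaged under `fluctnet/data/`.

## CLI

```bash
# generate a synthetic panel (multi-model PDBs + efficacy table + oracle)
fluctnet synth --out panel/ --seed 7

# full pipeline: RMSF/PCC -> deltas -> networks -> scores
fluctnet analyze --panel panel/ --out results/

# or stage by stage
fluctnet fluct   --panel panel/ --out results/
fluctnet delta   --panel panel/ --out results/
fluctnet network --panel panel/ --out results/ --threshold 0.6 --cutoff 12
fluctnet predict --panel panel/ --out results/ --regions regions.yaml
```

A panel directory contains `topology.pdb`, `segments.json|yaml`,
`efficacy.tsv` (columns `ligand_id`, `gprotein_emax`, `barrestin_emax`,
raw %), and `runs/<ligand>_<state>.pdb` multi-model ensembles (XTC/DCD
also readable through the same loader). Outputs are TSV/JSON plus a
deterministic manifest; logs go to stderr. Exit codes: 0 ok, 1 validation
error, 2 runtime failure.

Key options: `--threshold` / `--cutoff` for the network screens, `--mode
absolute|signed_positive` for how the correlation threshold is applied,
`--pcc-normalization sum|mean` (the `mean` variant divides the component
sum by 9 before the root), `--discard N` to drop leading equilibration
frames, and `--gprotein-weak-threshold` / `--gprotein-reference-emax` for
the classification bands.

## Library

```python
from fluctnet import SyntheticPanelConfig, generate_panel
from fluctnet.pipeline import analyze_records, toy_region_config
from fluctnet.prediction import load_region_config

panel = generate_panel(SyntheticPanelConfig(seed=7))
result = analyze_records(
    panel.topology, panel.records, panel.efficacy,
    regions=load_region_config(toy_region_config()),
)
result.networks["gprotein"].fluctuating_atoms  # [(atom_index, r), ...]
result.scores["barrestin"]                     # per-ligand score frame
```

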
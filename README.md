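# screensuite

Three desk-side toolkits for structure-based virtual-screening campaigns
against flexible targets (the motivating system is a protein–protein
interface on a small PDZ domain, whose NMR bundle samples several
conformational states):

1. **`screensuite.ensemble`** — conformational analysis of multi-model
   structure files. Models are superposed onto a reference by least-squares
   (Kabsch) fitting of backbone atoms (N, CA, C, O), and the pairwise
   backbone RMSD matrix is computed on the aligned coordinates. Outlier
   models are flagged by three orthogonal detectors — Tukey fences
   (Q1 − 1.5·IQR, Q3 + 1.5·IQR) on per-model mean RMSD, an Isolation Forest
   (contamination 0.1) on flattened coordinates, and Ward-linkage singleton
   detection at a μ + 2σ merge-height cut — with models flagged by ≥ 2
   methods excluded as consensus outliers. The cluster number k is chosen by
   silhouette maximization over k = 2…6 (Davies–Bouldin, Calinski–Harabasz
   and inertia are reported alongside), models are clustered by k-means
   (20 initializations), and each cluster's representative is chosen by a
   four-method vote (medoid, centroid proximity, minimax, density peak) and
   scored with a composite quality function
   `0.35·n_avg + 0.25·n_max + 0.25·coverage + 0.15·centrality`.
   Flexibility is summarized by per-model radius of gyration and
   per-residue RMSF, and the ensemble is projected with PCA.

2. **`screensuite.ligprep`** — turns raw SMILES tables into screening-ready
   SDF libraries: delimiter sniffing, standardization (largest organic
   fragment, charge neutralization, canonical tautomer), Lipinski
   rule-of-five and TPSA/rotatable-bond/Fsp3 drug-likeness filters,
   PAINS/BRENK/NIH structural alerts, net-charge rejection,
   canonical-SMILES deduplication and optional deterministic 3D embedding —
   with every rejection logged at its first failing stage.

3. **`screensuite.hitrank`** — consensus prioritization of hits scored by a
   docking score (Glide gscore) and an MM-GBSA binding free energy, both in
   kcal/mol with lower = better. Five rankings — equal-weight z-score,
   percentile, weighted z-score (0.4 docking / 0.6 MM-GBSA), Pareto
   frontier peeling, and strict dual cutoffs (gscore ≤ −6.0,
   ΔG ≤ −40.0 kcal/mol) — are averaged into an ensemble rank.

A fourth module, **`screensuite.fixtures`**, generates synthetic inputs
with planted ground truth (two-state conformer bundles, correlated score
tables, SMILES sets with known filter outcomes) so that every stage is
testable without downloads.

## Worked example

```sh
$ screensuite fixtures make-ensemble --out two_state.pdb --models 15 --outliers 1 --seed 7
$ screensuite ensemble analyze --pdb two_state.pdb --seed 7 --outdir ens_out
models=15 atoms=160 k=2 representatives=[1, 14] consensus_outliers=[15]
```

The generator planted two conformational states (12 + 2 models, 6 Å hinge
separation, 0.5 Å coordinate noise) plus one strongly deformed model. The
analysis recovers the two states (`k=2`), picks one representative per
state (models 1 and 14), and flags the planted outlier (model 15) by all
three detectors. `ens_out/` contains the full JSON report, the RMSD matrix
and RMSF CSV exports, the nine diagnostic panels, and a `manifest.json`
with input digests and the resolved configuration.

```sh
$ screensuite fixtures make-scores --out scores.csv --n 2000 --pass-fraction 0.456 --seed 7
scores.csv pass_count=912
$ screensuite hitrank run --in scores.csv --out ranked.csv
{"n": 2000, "pareto_front": ["CMPD000251", "CMPD000496", "CMPD000616", ...]}
```

`ranked.csv` holds the five per-method ranks, the ensemble rank and each
compound's Pareto frontier index; 912/2000 = 45.6 % of compounds pass the
strict dual cutoff, as planted.

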
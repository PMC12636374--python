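# Methods

This note documents the models and procedures implemented in screensuite,
the parameters that matter, the numerical choices made where the design
was genuinely open, and what the synthetic fixtures do and do not emulate.

## Ensemble conformational analysis

**Superposition.** Every model is rigidly fitted (rotation + translation,
no reflection) onto a reference model — by default the first model in the
file — by least-squares Kabsch fitting over the selected backbone atoms
(N, CA, C, O of one chain; altloc resolved to highest occupancy, first on
ties; insertion codes kept in residue keys). The pairwise RMSD matrix is
then computed **on the reference-aligned coordinates without per-pair
re-fitting**, matching the align-then-measure order of operations; a flag
(`per_pair_superposition=True`) switches to per-pair optimal fitting for
users who prefer the metrically cleaner variant. Ensemble statistics
(mean/SD/min/max) are taken over the off-diagonal upper triangle, each
unordered pair once; the SD uses ddof = 1.

**Outlier consensus.** Three detectors vote per model: (i) Tukey fences at
Q1 − 1.5·IQR / Q3 + 1.5·IQR on the per-model mean RMSD (linear-interpolated
quartiles; disabled with a warning below 4 models); (ii) an Isolation
Forest (100 trees, contamination 0.1, fixed seed recorded in the report)
on the flattened M×3A coordinate matrix; (iii) Ward-linkage clustering of
the RMSD matrix cut at μ + 2σ of the linkage merge heights, flagging
singleton clusters. Models with ≥ 2 votes are consensus outliers. The vote
is monotone by construction: adding a vote can never un-flag a model.

**Cluster number and clustering.** k-means (Euclidean, on flattened
aligned coordinates, 20 initializations) is evaluated for k = 2…6 on the
non-outlier models; silhouette, Davies–Bouldin, Calinski–Harabasz and
inertia are tabulated, and **silhouette alone decides k** — the other
indices are reported, not voted, because a single deciding criterion keeps
the selection reproducible and interpretable. Consensus outliers are
excluded from k-selection and the k-means fit, then assigned to their
nearest centroid but marked `excluded`, so occupancy counts cover all M
models while the fit itself is uncontaminated. Clusters are renumbered by
descending occupancy, making "cluster 0" always the dominant state. The
dendrogram panel uses Ward linkage on the RMSD matrix; k-means and the
internal indices use flattened-coordinate space.

**Representative selection.** Four selectors run per cluster — medoid
(min average RMSD to members), centroid proximity (min Euclidean distance
to the cluster's mean flattened coordinates), minimax (min of max RMSD),
and density peak (most members within the cluster's 25th-percentile
pairwise RMSD) — and the modal candidate wins, with ties broken toward the
medoid and then the lowest model id. Outliers assigned to a cluster are
measured against but are not eligible candidates.

**Quality score.** `0.35·n_avg + 0.25·n_max + 0.25·coverage +
0.15·centrality`, all components in [0, 1]. `n_avg`/`n_max` min–max
normalize the members' average/maximum RMSD with the best member mapped
to 1; components on which all members tie are set to 1 (so singleton and
symmetric two-member clusters score 1.000). Coverage is the fraction of
cluster members within 2 Å of the representative and **by default counts
the representative itself in both numerator and denominator** — under this
convention a 13-member cluster with 7 non-representative members within
2 Å reports 8/13 = 61.5 %, and a tight two-member cluster reports 100 %,
which keeps the perfect-score case consistent; an exclusive mode
(`coverage_includes_representative=False`) uses (members-within)/(n−1)
instead. Centrality is 1/rank of the representative when members are
sorted by average RMSD (the alternative (n−rank+1)/n reading was rejected
as it compresses differences in small clusters).

**Diversity and compactness.** Mean intra-cluster pairwise RMSD and
diameter (max pair) are standard; compactness has no canonical definition,
so the package uses mean intra-cluster RMSD divided by the global mean
pairwise RMSD (dimensionless, smaller = tighter), records the definition
name in the report, and excludes it from any acceptance-style comparison.
Singletons return (0, 0, 1) by convention.

**Flexibility.** Rg is mass-unweighted over the selected backbone atoms.
RMSF is computed per atom about the ensemble-mean position and averaged
within residues; both vectors are exported because multi-model files in
the wild are ambiguous about the intended axis. Residues above the 75th
percentile of the per-residue vector are flagged high-flexibility.

**Inter-representative RMSD** is the mean pairwise RMSD between cluster
representatives (a single number for the two-state case).

## Ligand preparation

Stage order (first failure wins, for interpretable logs):
**parse → standardize → Lipinski → drug-likeness → alerts → net-charge →
dedup**. The order is a design choice — cheap syntactic checks first,
then physicochemical bounds, then substructure screens.

* Standardization: RDKit `rdMolStandardize` cleanup, largest-organic-
  fragment selection, uncharging, canonical tautomer. The operation is
  idempotent (verified by test).
* Lipinski: MW ≤ 500, cLogP ≤ 5, HBD ≤ 5, HBA ≤ 10 (Lipinski N+O
  counting). Default is strict (0 violations); the classic ≤ 1-violation
  mode is a configuration switch.
* Drug-likeness: TPSA ≤ 140 Å², rotatable bonds ≤ 10, Fsp3 pass-through
  (min 0.0) unless raised. These cutoffs follow common screening practice;
  they are configurable and recorded in the log header rather than
  presented as canonical.
* Alerts: PAINS + BRENK + NIH catalogs via RDKit's FilterCatalog; any
  match rejects with the alert identifiers listed. Note that permanently
  charged species (e.g. quaternary ammonium) usually carry a BRENK
  quaternary-nitrogen alert and therefore fall at this stage; the
  net-charge stage catches charged molecules only when the catalogs are
  disabled or the pattern set misses them.
* Charge: "physiological-pH neutrality" is approximated as
  uncharge-then-reject-residual-net-charge; no pKa model is implemented.
  Net-zero zwitterions pass.
* 3D embedding: hydrogens are added before ETKDGv3 embedding with the
  run seed, making coordinates reproducible; failures are logged
  (`embed_failed`), never raised.

Parallel processing tags every work item with its input index and restores
input order before deduplication and writing, so the SDF is byte-identical
for any worker count. Record conservation (in = accepted + Σ per-stage
rejections) holds by construction and is asserted in tests.

## Hit ranking

All five methods produce average-tie fractional ranks so the ensemble mean
is unbiased. Percentile orientation maps "better" (more negative) to
higher percentiles. Dominance uses ≤/≤ with at least one strict
inequality; exact duplicates are mutually non-dominating and share a
frontier. Frontier peeling uses a sort-and-scan non-dominated extraction
per peel (O(n log n)), verified against a brute-force O(n²) oracle.
Strict-cutoff ranking z-ranks the passers among themselves; non-passers
are placed after all passers, ordered by their own z-score combination —
the cutoff description alone yields only a partial order, and ensemble
averaging needs a total one. Pareto levels are likewise converted to
fractional ranks before averaging so the five methods are commensurable.
Weights 0.4 (docking) / 0.6 (MM-GBSA) reflect the higher typical accuracy
of MM-GBSA estimates and are configurable.

## Synthetic fixtures: what they do and do not show

* **Two-state bundles** are geometric backbones (a helical polyline with
  idealized N/CA/C/O offsets), not physically valid proteins. Cluster
  separation is applied as a smooth hinge displacement over the second
  half of the chain, because a global translation/rotation would be
  removed by superposition; outliers use the same construction with a much
  larger amplitude. Isotropic Gaussian noise (default σ = 0.5 Å per
  coordinate) gives the closed-form atom RMSF √3·σ used as a test oracle.
  Passing these tests shows the geometry/clustering machinery is correct;
  it does not validate behavior on real NMR restraint artifacts or
  heterogeneous per-residue disorder.
* **Score tables** are bivariate normal with requested means, SDs and
  correlation (defaults: −6.80 ± 0.91 and −41.47 ± 9.65 kcal/mol,
  R = 0.363, n = 9353 — the scale of a post-docking hit list). When an
  exact dual-cutoff pass fraction is requested, the rows nearest the
  cutoff boundary are nudged minimally across it, perturbing the moments
  by far less than one standard error. Real score distributions are
  heavier-tailed and more structured than a Gaussian.
* **SMILES fixtures** are curated pools verified against RDKit descriptors
  and the published alert catalogs, one pool per first-failing stage;
  failing pools may be cycled (each repeated rejected row still logs at
  its stage), while planted passers are kept distinct. They exercise the
  pipeline's logic, not the chemical diversity of a vendor library.

## Problem sizes and determinism

Defaults were chosen at the scale of the motivating study: 15-model
bundles for the ensemble analysis, 9353-row score tables, 100-table
Pareto-oracle sweeps with n ≤ 500, and a 200-molecule preparation
library. Every stochastic step (fixture generation, Isolation Forest,
k-means, embedding) takes an explicit seed; a fixed seed and input make
the full pipelines bit-reproducible, and each CLI run writes a manifest
with the resolved configuration and input digests.

## Known limitations

* No docking, MD, MM-GBSA or pose analysis: the toolkits prepare inputs
  for and consume outputs of those engines.
* The ensemble module assumes all models share an identical atom list and
  refuses (rather than repairs) inconsistent multi-model files.
* The ligand pipeline has no pKa or protonation-state model, no
  stereoisomer/tautomer enumeration beyond the single canonical tautomer,
  and a 3D mode that embeds exactly one conformer.
* Internal clustering indices (silhouette etc.) are computed in flattened
  Cartesian space, which is only meaningful after superposition; the
  module enforces that ordering internally.
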
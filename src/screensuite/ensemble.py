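"""Conformational analysis of multi-model structure ensembles.

Workflow (mirroring common practice for NMR bundles): read the multi-model
PDB/mmCIF file keeping one chain's backbone atoms (N, CA, C, O); superpose
every model onto a reference model by least-squares (Kabsch) fitting;
compute the pairwise backbone RMSD matrix on the aligned coordinates;
flag outlier models by three orthogonal detectors (IQR on per-model mean
RMSD, Isolation Forest on flattened coordinates, Ward-linkage singleton
detection) and take a >=2-vote consensus; choose the cluster number k by
silhouette maximization over k = 2..6; cluster the non-outlier models with
k-means; pick one representative per cluster by a four-method vote (medoid,
centroid proximity, minimax, density peak) and score it with a weighted
composite quality function; summarize flexibility with per-model radius of
gyration and per-residue RMSF; and project the ensemble with PCA.

All distances are in Angstroms.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.spatial.transform import Rotation
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.ensemble import IsolationForest
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

BACKBONE_ATOMS = ("N", "CA", "C", "O")

__all__ = [
    "BACKBONE_ATOMS",
    "ConformerEnsemble",
    "RMSDMatrix",
    "RMSDSummary",
    "OutlierReport",
    "FlexibilityProfile",
    "ClusterReport",
    "EnsembleConfig",
    "read_multimodel_pdb",
    "superpose_kabsch",
    "pairwise_rmsd_matrix",
    "ensemble_rmsd_summary",
    "radius_of_gyration",
    "per_residue_rmsf",
    "outliers_iqr",
    "outliers_isolation_forest",
    "outliers_hier_singleton",
    "consensus_outliers",
    "choose_k",
    "cluster_kmeans",
    "select_representative",
    "representative_quality",
    "cluster_diversity",
    "pca_project",
    "analyze_ensemble",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConformerEnsemble:
    """Backbone coordinates of M conformers sharing one atom list.

    Parameters
    ----------
    model_ids
        Model numbers as they appear in the source file (usually 1-based).
    coords
        Array of shape (M, A, 3) in Angstroms.
    atom_labels
        One ``(chain_id, residue_key, atom_name)`` triple per atom; the
        residue key is the residue number with any insertion code appended.
    reference_index
        Index (into ``model_ids``) of the superposition reference.
    """

    model_ids: tuple[int, ...]
    coords: np.ndarray
    atom_labels: tuple[tuple[str, str, str], ...]
    reference_index: int = 0

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValueError("coords must have shape (M, A, 3)")
        if coords.shape[0] != len(self.model_ids):
            raise ValueError("coords and model_ids disagree on model count")
        if coords.shape[1] != len(self.atom_labels):
            raise ValueError("coords and atom_labels disagree on atom count")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        if not 0 <= self.reference_index < len(self.model_ids):
            raise ValueError("reference_index out of range")

    @property
    def n_models(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def flattened(self) -> np.ndarray:
        """Coordinates as an (M, 3A) matrix for clustering and PCA."""
        return self.coords.reshape(self.n_models, -1)

    def residue_keys(self) -> list[str]:
        """Unique residue keys in chain order."""
        seen: dict[str, None] = {}
        for _, res, _ in self.atom_labels:
            seen.setdefault(res, None)
        return list(seen)


@dataclass(frozen=True)
class RMSDMatrix:
    """Symmetric M x M pairwise backbone RMSD matrix (Angstroms)."""

    values: np.ndarray
    model_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("RMSD matrix must be square")
        if v.shape[0] != len(self.model_ids):
            raise ValueError("matrix size and model_ids disagree")
        if not np.allclose(v, v.T, atol=1e-8):
            raise ValueError("RMSD matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-8):
            raise ValueError("RMSD matrix diagonal must be zero")
        if np.any(v < -1e-12):
            raise ValueError("RMSD values must be non-negative")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class RMSDSummary:
    mean: float
    sd: float
    min: float
    max: float
    per_model_mean: np.ndarray


@dataclass(frozen=True)
class OutlierReport:
    """Per-model outlier flags from three detectors plus their consensus."""

    iqr: np.ndarray
    isolation_forest: np.ndarray
    hier_singleton: np.ndarray
    consensus: np.ndarray
    method_params: dict

    def votes(self) -> np.ndarray:
        return (
            self.iqr.astype(int)
            + self.isolation_forest.astype(int)
            + self.hier_singleton.astype(int)
        )


@dataclass(frozen=True)
class FlexibilityProfile:
    """Radius-of-gyration and RMSF flexibility summary."""

    rg_per_model: np.ndarray
    rmsf_per_atom: np.ndarray
    rmsf_per_residue: np.ndarray
    residue_keys: tuple[str, ...]
    rmsf_mean: float
    high_flex_residues: tuple[str, ...]


@dataclass
class ClusterReport:
    """Clustering outcome: labels, k-selection metrics, representatives."""

    k: int
    labels: np.ndarray  # cluster id per model, outliers nearest-centroid assigned
    excluded: np.ndarray  # True for consensus outliers
    k_metrics: pd.DataFrame
    occupancies: dict[int, int]
    representatives: dict[int, int]  # cluster id -> model id
    representative_votes: dict[int, dict[str, int]]
    quality_scores: dict[int, float]
    quality_components: dict[int, dict[str, float]]
    diversity: dict[int, dict[str, float]]
    inter_representative_rmsd: float
    pca_coords: np.ndarray
    pca_explained_variance_ratio: np.ndarray
    silhouette: float
    davies_bouldin: float


@dataclass
class EnsembleConfig:
    """Tunable parameters of :func:`analyze_ensemble`."""

    chain: str = "A"
    atom_names: tuple[str, ...] = BACKBONE_ATOMS
    k_min: int = 2
    k_max: int = 6
    n_init: int = 20
    seed: int = 42
    iqr_factor: float = 1.5
    contamination: float = 0.1
    n_estimators: int = 100
    singleton_sigma: float = 2.0
    consensus_min_votes: int = 2
    coverage_cutoff: float = 2.0
    coverage_includes_representative: bool = True
    per_pair_superposition: bool = False
    make_plots: bool = True


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------


def read_multimodel_pdb(
    path: str | Path,
    chain: str = "A",
    atom_names: Sequence[str] = BACKBONE_ATOMS,
) -> ConformerEnsemble:
    """Read a multi-model PDB or mmCIF file into a :class:`ConformerEnsemble`.

    Keeps only the requested chain and atom names. Alternate locations are
    resolved to the highest-occupancy conformer (first on ties); insertion
    codes are retained in the residue key. Models whose atom list differs
    from the first model raise ``ValueError`` rather than being silently
    truncated.
    """
    import gemmi

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    structure = gemmi.read_structure(str(path))
    if len(structure) < 2:
        raise ValueError(
            f"{path.name}: expected a multi-model file (>= 2 MODEL records), "
            f"found {len(structure)}"
        )
    wanted = set(atom_names)

    model_ids: list[int] = []
    labels_per_model: list[list[tuple[str, str, str]]] = []
    coords_per_model: list[np.ndarray] = []
    for model in structure:
        ch = model.find_chain(chain)
        if ch is None:
            raise ValueError(f"{path.name}: chain {chain!r} absent in model {model.num}")
        labels: list[tuple[str, str, str]] = []
        xyz: list[tuple[float, float, float]] = []
        for residue in ch:
            reskey = str(residue.seqid.num) + (
                residue.seqid.icode.strip() if residue.seqid.icode else ""
            )
            by_name: dict[str, gemmi.Atom] = {}
            for atom in residue:
                if atom.name not in wanted:
                    continue
                prev = by_name.get(atom.name)
                if prev is None or atom.occ > prev.occ:  # first wins ties
                    by_name[atom.name] = atom
            for name in atom_names:
                if name in by_name:
                    a = by_name[name]
                    labels.append((chain, reskey, name))
                    xyz.append((a.pos.x, a.pos.y, a.pos.z))
        model_ids.append(model.num)
        labels_per_model.append(labels)
        coords_per_model.append(np.array(xyz, dtype=float).reshape(-1, 3))

    reference = labels_per_model[0]
    for mid, labels in zip(model_ids, labels_per_model):
        if labels != reference:
            raise ValueError(
                f"{path.name}: inconsistent atom lists across models "
                f"(model {mid} differs from model {model_ids[0]})"
            )
    return ConformerEnsemble(
        model_ids=tuple(model_ids),
        coords=np.stack(coords_per_model),
        atom_labels=tuple(reference),
        reference_index=0,
    )


# ---------------------------------------------------------------------------
# superposition and RMSD
# ---------------------------------------------------------------------------


def _kabsch_fit(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rigidly fit ``mobile`` onto ``target`` (both (A, 3)); returns moved coords.

    Least-squares optimal proper rotation (no reflection) plus translation.
    """
    mu_m = mobile.mean(axis=0)
    mu_t = target.mean(axis=0)
    with warnings.catch_warnings():
        # align_vectors warns for exact/rank-deficient fits; the estimate is fine
        warnings.simplefilter("ignore", UserWarning)
        rot, _ = Rotation.align_vectors(target - mu_t, mobile - mu_m)
    return rot.apply(mobile - mu_m) + mu_t


def superpose_kabsch(ensemble: ConformerEnsemble) -> ConformerEnsemble:
    """Superpose every model onto the reference model.

    The reference model is returned unchanged; every other model is rigidly
    transformed (rotation + translation) to minimize its RMSD to the
    reference over all atoms.
    """
    if ensemble.n_models < 2:
        raise ValueError("superposition needs >= 2 models")
    if ensemble.n_atoms < 3:
        raise ValueError("superposition needs >= 3 atoms")
    ref = ensemble.coords[ensemble.reference_index]
    centered = ref - ref.mean(axis=0)
    # collinear (rank < 2) geometry leaves the rotation under-determined
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise ValueError("degenerate geometry: atoms are collinear")
    moved = np.empty_like(ensemble.coords)
    for i in range(ensemble.n_models):
        if i == ensemble.reference_index:
            moved[i] = ref
        else:
            moved[i] = _kabsch_fit(ensemble.coords[i], ref)
    return ConformerEnsemble(
        model_ids=ensemble.model_ids,
        coords=moved,
        atom_labels=ensemble.atom_labels,
        reference_index=ensemble.reference_index,
    )


def rmsd_between(a: np.ndarray, b: np.ndarray) -> float:
    """Plain coordinate RMSD between two (A, 3) arrays, no fitting."""
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def pairwise_rmsd_matrix(
    ensemble: ConformerEnsemble, per_pair_superposition: bool = False
) -> RMSDMatrix:
    """Pairwise RMSD over all atoms between every model pair.

    By default the matrix is computed on the coordinates as given (i.e.
    after one global superposition to the reference); with
    ``per_pair_superposition=True`` each pair is re-fit before measuring.
    """
    m = ensemble.n_models
    values = np.zeros((m, m), dtype=float)
    for i in range(m):
        for j in range(i + 1, m):
            a, b = ensemble.coords[i], ensemble.coords[j]
            if per_pair_superposition:
                b = _kabsch_fit(b, a)
            values[i, j] = values[j, i] = rmsd_between(a, b)
    return RMSDMatrix(values=values, model_ids=ensemble.model_ids)


def ensemble_rmsd_summary(matrix: RMSDMatrix) -> RMSDSummary:
    """Mean/SD/min/max over off-diagonal pairs plus per-model mean RMSD.

    Each unordered pair is counted once; the SD is the sample standard
    deviation (ddof = 1). ``per_model_mean[i]`` is the mean of row i
    excluding the diagonal.
    """
    if matrix.n < 2:
        raise ValueError("need at least two models")
    iu = np.triu_indices(matrix.n, k=1)
    offdiag = matrix.values[iu]
    per_model = (matrix.values.sum(axis=1)) / (matrix.n - 1)
    return RMSDSummary(
        mean=float(offdiag.mean()),
        sd=float(offdiag.std(ddof=1)) if offdiag.size > 1 else 0.0,
        min=float(offdiag.min()),
        max=float(offdiag.max()),
        per_model_mean=per_model,
    )


# ---------------------------------------------------------------------------
# flexibility
# ---------------------------------------------------------------------------


def radius_of_gyration(coords: np.ndarray) -> float:
    """Mass-unweighted radius of gyration of one model's coordinates."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 1:
        raise ValueError("coords must be a non-empty (A, 3) array")
    centroid = coords.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((coords - centroid) ** 2, axis=1))))


def per_residue_rmsf(ensemble: ConformerEnsemble) -> FlexibilityProfile:
    """RMSF about the ensemble-mean position, per atom and per residue.

    Per-atom RMSF is the root-mean-square (over models) deviation from the
    atom's mean position; per-residue values average that residue's backbone
    atoms. Residues above the 75th percentile of the per-residue vector are
    flagged as high-flexibility.
    """
    if ensemble.n_models < 2:
        warnings.warn("single-model ensemble: RMSF is identically zero")
    mean_pos = ensemble.coords.mean(axis=0)
    dev2 = np.sum((ensemble.coords - mean_pos) ** 2, axis=2)  # (M, A)
    rmsf_atom = np.sqrt(dev2.mean(axis=0))

    keys = ensemble.residue_keys()
    key_index = {k: i for i, k in enumerate(keys)}
    sums = np.zeros(len(keys))
    counts = np.zeros(len(keys))
    for atom_i, (_, res, _) in enumerate(ensemble.atom_labels):
        j = key_index[res]
        sums[j] += rmsf_atom[atom_i]
        counts[j] += 1
    rmsf_res = sums / counts
    threshold = np.percentile(rmsf_res, 75)
    high = tuple(k for k, v in zip(keys, rmsf_res) if v > threshold)
    rg = np.array([radius_of_gyration(c) for c in ensemble.coords])
    return FlexibilityProfile(
        rg_per_model=rg,
        rmsf_per_atom=rmsf_atom,
        rmsf_per_residue=rmsf_res,
        residue_keys=tuple(keys),
        rmsf_mean=float(rmsf_res.mean()),
        high_flex_residues=high,
    )


# ---------------------------------------------------------------------------
# outlier detection
# ---------------------------------------------------------------------------


def outliers_iqr(per_model_mean: np.ndarray, factor: float = 1.5) -> np.ndarray:
    """Tukey-fence flags on the per-model mean RMSD vector."""
    x = np.asarray(per_model_mean, dtype=float)
    if x.size < 4:
        warnings.warn("fewer than 4 models: IQR outlier detection disabled")
        return np.zeros(x.size, dtype=bool)
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    return (x < q1 - factor * iqr) | (x > q3 + factor * iqr)


def outliers_isolation_forest(
    flattened: np.ndarray,
    contamination: float = 0.1,
    seed: int = 42,
    n_estimators: int = 100,
) -> np.ndarray:
    """Isolation-Forest anomaly flags on flattened (M, 3A) coordinates."""
    x = np.asarray(flattened, dtype=float)
    if x.shape[0] < 3:
        raise ValueError("Isolation Forest needs >= 3 models")
    forest = IsolationForest(
        contamination=contamination, n_estimators=n_estimators, random_state=seed
    )
    return forest.fit_predict(x) == -1


def outliers_hier_singleton(
    matrix: RMSDMatrix, sigma_factor: float = 2.0
) -> np.ndarray:
    """Singleton flags from a Ward dendrogram cut at mu + sigma_factor*sigma.

    The linkage is built on the pairwise RMSD matrix; mu and sigma are taken
    over the linkage merge heights; every cluster of size one at that cut is
    flagged.
    """
    if matrix.n < 3:
        raise ValueError("hierarchical singleton detection needs >= 3 models")
    condensed = squareform(matrix.values, checks=False)
    linkage = hierarchy.linkage(condensed, method="ward")
    heights = linkage[:, 2]
    cut = heights.mean() + sigma_factor * heights.std(ddof=0)
    labels = hierarchy.fcluster(linkage, t=cut, criterion="distance")
    sizes = np.bincount(labels)
    return sizes[labels] == 1


def consensus_outliers(
    iqr_flags: np.ndarray,
    forest_flags: np.ndarray,
    singleton_flags: np.ndarray,
    min_votes: int = 2,
    method_params: dict | None = None,
) -> OutlierReport:
    """Combine the three detectors: consensus = flagged by >= ``min_votes``."""
    iqr_flags = np.asarray(iqr_flags, dtype=bool)
    forest_flags = np.asarray(forest_flags, dtype=bool)
    singleton_flags = np.asarray(singleton_flags, dtype=bool)
    votes = iqr_flags.astype(int) + forest_flags.astype(int) + singleton_flags.astype(int)
    params = {"consensus_min_votes": min_votes}
    if method_params:
        params.update(method_params)
    return OutlierReport(
        iqr=iqr_flags,
        isolation_forest=forest_flags,
        hier_singleton=singleton_flags,
        consensus=votes >= min_votes,
        method_params=params,
    )


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


def choose_k(
    flattened: np.ndarray,
    k_range: Sequence[int] = range(2, 7),
    seed: int = 42,
    n_init: int = 20,
) -> tuple[int, pd.DataFrame]:
    """Evaluate k-means over ``k_range`` and pick k by silhouette maximization.

    Returns the chosen k and a per-k table of silhouette, Davies-Bouldin,
    Calinski-Harabasz and inertia. k values that would exceed n_samples - 1
    are dropped (with a warning) rather than evaluated.
    """
    x = np.asarray(flattened, dtype=float)
    n = x.shape[0]
    ks = [k for k in k_range if 2 <= k <= n - 1]
    if not ks:
        raise ValueError(f"no feasible k in {list(k_range)} for {n} samples")
    if len(ks) < len(list(k_range)):
        warnings.warn(f"k range truncated to {ks} for {n} samples")
    rows = []
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        labels = km.fit_predict(x)
        if len(np.unique(labels)) < 2:
            continue
        rows.append(
            {
                "k": k,
                "silhouette": silhouette_score(x, labels),
                "davies_bouldin": davies_bouldin_score(x, labels),
                "calinski_harabasz": calinski_harabasz_score(x, labels),
                "inertia": km.inertia_,
            }
        )
    table = pd.DataFrame(rows).set_index("k")
    best_k = int(table["silhouette"].idxmax())
    return best_k, table


def cluster_kmeans(
    flattened: np.ndarray,
    k: int,
    outlier_mask: np.ndarray | None = None,
    n_init: int = 20,
    seed: int = 42,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """k-means over non-outlier models; outliers get a nearest-centroid label.

    Returns ``(labels, excluded, centroids)``. Cluster ids are renumbered by
    descending occupancy (counting all models, assigned outliers included)
    so that cluster 0 is always the dominant state.
    """
    x = np.asarray(flattened, dtype=float)
    m = x.shape[0]
    excluded = (
        np.zeros(m, dtype=bool) if outlier_mask is None else np.asarray(outlier_mask, bool)
    )
    fit_x = x[~excluded]
    if fit_x.shape[0] < k:
        raise ValueError(f"cannot form {k} clusters from {fit_x.shape[0]} models")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    fit_labels = km.fit_predict(fit_x)
    labels = np.empty(m, dtype=int)
    labels[~excluded] = fit_labels
    if excluded.any():
        d = np.linalg.norm(x[excluded][:, None, :] - km.cluster_centers_[None], axis=2)
        labels[excluded] = d.argmin(axis=1)
    # renumber by descending occupancy over all models; ties by old id
    counts = np.bincount(labels, minlength=k)
    order = np.lexsort((np.arange(k), -counts))
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    return remap[labels], excluded, km.cluster_centers_[order]


# ---------------------------------------------------------------------------
# representatives
# ---------------------------------------------------------------------------


def select_representative(
    member_indices: Sequence[int],
    matrix: RMSDMatrix,
    flattened: np.ndarray,
    candidate_indices: Sequence[int] | None = None,
    density_percentile: float = 25.0,
) -> tuple[int, dict[str, int]]:
    """Pick a cluster representative by a four-method vote.

    The four candidates are the medoid (minimum average RMSD to members),
    the centroid-proximal member (minimum Euclidean distance of flattened
    coordinates to the cluster mean), the minimax member (minimum of maximum
    RMSD to members), and the density peak (most members within the cluster's
    25th-percentile pairwise RMSD). The modal candidate wins; ties break in
    favor of the medoid, then the lowest index. ``candidate_indices``
    restricts eligibility (e.g. to non-outlier members); distances are still
    measured against every member.

    Returns ``(representative_index, votes)`` where votes maps method name to
    the index that method selected.
    """
    members = list(member_indices)
    if not members:
        raise ValueError("empty cluster")
    cands = list(candidate_indices) if candidate_indices is not None else members
    cands = [c for c in cands if c in members] or members
    sub = matrix.values[np.ix_(members, members)]
    pos = {m: i for i, m in enumerate(members)}

    avg = sub.mean(axis=1) * len(members) / max(len(members) - 1, 1)  # exclude self
    mx = sub.max(axis=1)
    mean_coord = np.asarray(flattened, float)[members].mean(axis=0)
    cdist = np.linalg.norm(np.asarray(flattened, float)[members] - mean_coord, axis=1)
    pair_vals = sub[np.triu_indices(len(members), k=1)]
    radius = np.percentile(pair_vals, density_percentile) if pair_vals.size else 0.0
    density = (sub <= radius).sum(axis=1) - 1  # exclude self

    cand_rows = [pos[c] for c in cands]

    def _argbest(values: np.ndarray, maximize: bool = False) -> int:
        vals = values[cand_rows]
        best = np.argmax(vals) if maximize else np.argmin(vals)
        return cands[int(best)]

    votes = {
        "medoid": _argbest(avg),
        "centroid": _argbest(cdist),
        "minimax": _argbest(mx),
        "density_peak": _argbest(density, maximize=True),
    }
    tally: dict[int, int] = {}
    for v in votes.values():
        tally[v] = tally.get(v, 0) + 1
    top = max(tally.values())
    tied = sorted(i for i, c in tally.items() if c == top)
    if votes["medoid"] in tied:
        rep = votes["medoid"]
    else:
        rep = tied[0]
    return rep, votes


def representative_quality(
    rep_index: int,
    member_indices: Sequence[int],
    matrix: RMSDMatrix,
    coverage_cutoff: float = 2.0,
    include_rep_in_coverage: bool = True,
) -> tuple[float, dict[str, float]]:
    """Composite representative quality score in [0, 1].

    score = 0.35 * n_avg + 0.25 * n_max + 0.25 * coverage + 0.15 * centrality

    where n_avg and n_max min-max normalize the members' average and maximum
    RMSD to the rest of the cluster (best member -> 1, worst -> 0), coverage
    is the fraction of cluster members within ``coverage_cutoff`` of the
    representative (the representative itself counts toward both sides by
    default; ``include_rep_in_coverage=False`` drops it from numerator and
    denominator), and centrality is 1/rank of the representative when
    members are sorted by average RMSD. Components on which all members tie
    are set to 1.
    """
    members = list(member_indices)
    if rep_index not in members:
        raise ValueError("representative must belong to the cluster")
    n = len(members)
    if n == 1:
        comps = {"n_avg": 1.0, "n_max": 1.0, "coverage": 1.0, "centrality": 1.0}
        return 1.0, comps
    sub = matrix.values[np.ix_(members, members)]
    pos = members.index(rep_index)
    avg = sub.sum(axis=1) / (n - 1)
    mx = sub.max(axis=1)

    def _norm(values: np.ndarray) -> float:
        lo, hi = values.min(), values.max()
        if np.isclose(hi, lo):
            return 1.0
        return float((hi - values[pos]) / (hi - lo))

    n_avg = _norm(avg)
    n_max = _norm(mx)

    within = matrix.values[rep_index, members] <= coverage_cutoff
    if include_rep_in_coverage:
        coverage = float(within.sum()) / n  # rep trivially within of itself
    else:
        mask = np.array(members) != rep_index
        coverage = float(within[mask].sum()) / (n - 1)

    if np.allclose(avg, avg[0]):
        centrality = 1.0
    else:
        rank = 1 + int((avg < avg[pos]).sum())
        centrality = 1.0 / rank

    comps = {
        "n_avg": n_avg,
        "n_max": n_max,
        "coverage": coverage,
        "centrality": centrality,
    }
    score = 0.35 * n_avg + 0.25 * n_max + 0.25 * coverage + 0.15 * centrality
    return float(score), comps


def cluster_diversity(
    member_indices: Sequence[int],
    matrix: RMSDMatrix,
    global_mean_rmsd: float | None = None,
) -> dict[str, float]:
    """Intra-cluster diversity: mean pairwise RMSD, diameter, compactness.

    Compactness is defined here as mean intra-cluster RMSD divided by the
    global mean pairwise RMSD (dimensionless; smaller = tighter). Singleton
    clusters return (0, 0, 1) by convention.
    """
    members = list(member_indices)
    if len(members) == 1:
        return {"mean_intra_rmsd": 0.0, "diameter": 0.0, "compactness": 1.0}
    sub = matrix.values[np.ix_(members, members)]
    pairs = sub[np.triu_indices(len(members), k=1)]
    mean_intra = float(pairs.mean())
    if global_mean_rmsd is None:
        global_mean_rmsd = ensemble_rmsd_summary(matrix).mean
    compactness = mean_intra / global_mean_rmsd if global_mean_rmsd > 0 else 1.0
    return {
        "mean_intra_rmsd": mean_intra,
        "diameter": float(pairs.max()),
        "compactness": float(compactness),
    }


def pca_project(flattened: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean-centered PCA of flattened coordinates.

    Returns the first two component scores (M, 2) and the full vector of
    explained-variance ratios (which sums to 1 over all components).
    """
    x = np.asarray(flattened, dtype=float)
    n_comp = min(x.shape[0] - 1, x.shape[1])
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(x)
    evr = pca.explained_variance_ratio_
    if scores.shape[1] < 2:  # rank-1 data: pad PC2 with zeros
        scores = np.hstack([scores, np.zeros((x.shape[0], 2 - scores.shape[1]))])
    return scores[:, :2], evr


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


@dataclass
class EnsembleReport:
    """Everything :func:`analyze_ensemble` computes, JSON-serializable."""

    source: str
    config: EnsembleConfig
    model_ids: tuple[int, ...]
    n_atoms: int
    rmsd_matrix: RMSDMatrix
    rmsd_summary: RMSDSummary
    outliers: OutlierReport
    clusters: ClusterReport
    flexibility: FlexibilityProfile

    def consensus_outlier_ids(self) -> list[int]:
        return [m for m, f in zip(self.model_ids, self.outliers.consensus) if f]

    def representative_ids(self) -> list[int]:
        return [self.clusters.representatives[c] for c in sorted(self.clusters.representatives)]

    def to_dict(self) -> dict:
        c = self.clusters
        return {
            "source": self.source,
            "config": asdict(self.config),
            "model_ids": list(self.model_ids),
            "n_atoms": self.n_atoms,
            "rmsd_matrix": self.rmsd_matrix.values.tolist(),
            "rmsd_summary": {
                "mean": self.rmsd_summary.mean,
                "sd": self.rmsd_summary.sd,
                "min": self.rmsd_summary.min,
                "max": self.rmsd_summary.max,
                "per_model_mean": self.rmsd_summary.per_model_mean.tolist(),
            },
            "outliers": {
                "iqr": self.outliers.iqr.tolist(),
                "isolation_forest": self.outliers.isolation_forest.tolist(),
                "hier_singleton": self.outliers.hier_singleton.tolist(),
                "consensus": self.outliers.consensus.tolist(),
                "consensus_model_ids": self.consensus_outlier_ids(),
                "method_params": self.outliers.method_params,
            },
            "clusters": {
                "k": c.k,
                "labels": c.labels.tolist(),
                "excluded": c.excluded.tolist(),
                "k_metrics": c.k_metrics.reset_index().to_dict(orient="records"),
                "occupancies": {str(k): v for k, v in c.occupancies.items()},
                "representatives": {str(k): v for k, v in c.representatives.items()},
                "representative_votes": {
                    str(k): v for k, v in c.representative_votes.items()
                },
                "quality_scores": {str(k): v for k, v in c.quality_scores.items()},
                "quality_components": {
                    str(k): v for k, v in c.quality_components.items()
                },
                "diversity": {str(k): v for k, v in c.diversity.items()},
                "inter_representative_rmsd": c.inter_representative_rmsd,
                "silhouette": c.silhouette,
                "davies_bouldin": c.davies_bouldin,
                "pca_coords": c.pca_coords.tolist(),
                "pca_explained_variance_ratio": c.pca_explained_variance_ratio.tolist(),
            },
            "flexibility": {
                "rg_per_model": self.flexibility.rg_per_model.tolist(),
                "rmsf_per_atom": self.flexibility.rmsf_per_atom.tolist(),
                "rmsf_per_residue": self.flexibility.rmsf_per_residue.tolist(),
                "residue_keys": list(self.flexibility.residue_keys),
                "rmsf_mean": self.flexibility.rmsf_mean,
                "high_flex_residues": list(self.flexibility.high_flex_residues),
            },
        }


def analyze_ensemble(
    path: str | Path,
    config: EnsembleConfig | None = None,
    outdir: str | Path | None = None,
) -> EnsembleReport:
    """Run the full ensemble analysis on a multi-model structure file.

    Deterministic given (input file, config). When ``outdir`` is given, a
    JSON report, CSV exports of the RMSD matrix and RMSF vectors, and the
    nine diagnostic plot panels are written there.
    """
    cfg = config or EnsembleConfig()
    try:
        ens = read_multimodel_pdb(path, chain=cfg.chain, atom_names=cfg.atom_names)
    except Exception as exc:
        raise type(exc)(f"[read stage] {exc}") from exc

    ens = superpose_kabsch(ens)
    matrix = pairwise_rmsd_matrix(ens, per_pair_superposition=cfg.per_pair_superposition)
    summary = ensemble_rmsd_summary(matrix)
    flat = ens.flattened()

    outrep = consensus_outliers(
        outliers_iqr(summary.per_model_mean, factor=cfg.iqr_factor),
        outliers_isolation_forest(
            flat, contamination=cfg.contamination, seed=cfg.seed,
            n_estimators=cfg.n_estimators,
        ),
        outliers_hier_singleton(matrix, sigma_factor=cfg.singleton_sigma),
        min_votes=cfg.consensus_min_votes,
        method_params={
            "iqr_factor": cfg.iqr_factor,
            "contamination": cfg.contamination,
            "singleton_sigma": cfg.singleton_sigma,
            "isolation_forest_seed": cfg.seed,
            "n_estimators": cfg.n_estimators,
        },
    )
    keep = ~outrep.consensus

    k, k_metrics = choose_k(
        flat[keep], k_range=range(cfg.k_min, cfg.k_max + 1),
        seed=cfg.seed, n_init=cfg.n_init,
    )
    labels, excluded, _ = cluster_kmeans(
        flat, k, outlier_mask=outrep.consensus, n_init=cfg.n_init, seed=cfg.seed
    )
    sil = float(silhouette_score(flat[keep], labels[keep])) if k > 1 else float("nan")
    dbi = float(davies_bouldin_score(flat[keep], labels[keep])) if k > 1 else float("nan")

    occupancies = {c: int((labels == c).sum()) for c in range(k)}
    reps: dict[int, int] = {}
    votes: dict[int, dict[str, int]] = {}
    quality: dict[int, float] = {}
    quality_comps: dict[int, dict[str, float]] = {}
    diversity: dict[int, dict[str, float]] = {}
    for c in range(k):
        members = np.where(labels == c)[0].tolist()
        candidates = [m for m in members if not excluded[m]] or members
        rep, v = select_representative(members, matrix, flat, candidate_indices=candidates)
        q, comps = representative_quality(
            rep, members, matrix,
            coverage_cutoff=cfg.coverage_cutoff,
            include_rep_in_coverage=cfg.coverage_includes_representative,
        )
        reps[c] = int(ens.model_ids[rep])
        votes[c] = {name: int(ens.model_ids[i]) for name, i in v.items()}
        quality[c] = q
        quality_comps[c] = comps
        diversity[c] = cluster_diversity(members, matrix, summary.mean)

    rep_indices = [ens.model_ids.index(reps[c]) for c in sorted(reps)]
    if len(rep_indices) >= 2:
        inter = float(
            np.mean(
                [
                    matrix.values[i, j]
                    for a, i in enumerate(rep_indices)
                    for j in rep_indices[a + 1:]
                ]
            )
        )
    else:
        inter = 0.0

    pca_coords, evr = pca_project(flat)
    clusters = ClusterReport(
        k=k,
        labels=labels,
        excluded=excluded,
        k_metrics=k_metrics,
        occupancies=occupancies,
        representatives=reps,
        representative_votes=votes,
        quality_scores=quality,
        quality_components=quality_comps,
        diversity=diversity,
        inter_representative_rmsd=inter,
        pca_coords=pca_coords,
        pca_explained_variance_ratio=evr,
        silhouette=sil,
        davies_bouldin=dbi,
    )
    flex = per_residue_rmsf(ens)
    report = EnsembleReport(
        source=str(path),
        config=cfg,
        model_ids=ens.model_ids,
        n_atoms=ens.n_atoms,
        rmsd_matrix=matrix,
        rmsd_summary=summary,
        outliers=outrep,
        clusters=clusters,
        flexibility=flex,
    )
    if outdir is not None:
        _write_outputs(report, Path(outdir), make_plots=cfg.make_plots)
    return report


def _write_outputs(report: EnsembleReport, outdir: Path, make_plots: bool = True) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "ensemble_report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
    ids = [f"model_{m}" for m in report.model_ids]
    pd.DataFrame(report.rmsd_matrix.values, index=ids, columns=ids).to_csv(
        outdir / "rmsd_matrix.csv"
    )
    pd.DataFrame(
        {
            "residue": report.flexibility.residue_keys,
            "rmsf": report.flexibility.rmsf_per_residue,
        }
    ).to_csv(outdir / "rmsf_per_residue.csv", index=False)
    if make_plots:
        plot_ensemble_panels(report, outdir / "plots")


def plot_ensemble_panels(report: EnsembleReport, plotdir: Path) -> list[Path]:
    """Render the nine diagnostic panels (one PNG each)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plotdir = Path(plotdir)
    plotdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    c = report.clusters
    models = list(report.model_ids)
    rep_ids = set(report.representative_ids())
    out_ids = set(report.consensus_outlier_ids())

    def _save(fig, name):
        p = plotdir / name
        fig.savefig(p, dpi=100, bbox_inches="tight")
        plt.close(fig)
        written.append(p)

    # A: per-model mean RMSD
    fig, ax = plt.subplots(figsize=(6, 3.5))
    colors = [
        "crimson" if m in out_ids else ("goldenrod" if m in rep_ids else "steelblue")
        for m in models
    ]
    ax.bar([str(m) for m in models], report.rmsd_summary.per_model_mean, color=colors)
    ax.set_xlabel("model"); ax.set_ylabel("mean RMSD to others (Å)")
    _save(fig, "A_per_model_mean_rmsd.png")

    # B: cluster occupancy
    fig, ax = plt.subplots(figsize=(4, 3.5))
    occ = [c.occupancies[i] for i in sorted(c.occupancies)]
    ax.bar([f"cluster {i}" for i in sorted(c.occupancies)], occ)
    ax.set_ylabel("models")
    _save(fig, "B_cluster_occupancy.png")

    # C: k-selection metrics
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(c.k_metrics.index, c.k_metrics["silhouette"], "o-", label="silhouette")
    ax2 = ax.twinx()
    ax2.plot(c.k_metrics.index, c.k_metrics["davies_bouldin"], "s-", color="crimson",
             label="Davies-Bouldin")
    ax.axvline(c.k, color="green", linestyle="--")
    ax.set_xlabel("k"); ax.set_ylabel("silhouette"); ax2.set_ylabel("Davies-Bouldin")
    _save(fig, "C_k_selection.png")

    # D: PCA projection
    fig, ax = plt.subplots(figsize=(4.5, 4))
    evr = c.pca_explained_variance_ratio
    sc = ax.scatter(c.pca_coords[:, 0], c.pca_coords[:, 1], c=c.labels, cmap="tab10")
    for i, m in enumerate(models):
        ax.annotate(str(m), c.pca_coords[i], fontsize=7)
    ax.set_xlabel(f"PC1 ({100 * evr[0]:.1f} %)")
    ax.set_ylabel(f"PC2 ({100 * evr[1]:.1f} %)" if len(evr) > 1 else "PC2")
    fig.colorbar(sc, label="cluster")
    _save(fig, "D_pca_projection.png")

    # E: Ward dendrogram on the RMSD matrix
    fig, ax = plt.subplots(figsize=(6, 3.5))
    link = hierarchy.linkage(squareform(report.rmsd_matrix.values, checks=False), "ward")
    hierarchy.dendrogram(link, labels=[str(m) for m in models], ax=ax)
    ax.set_ylabel("Ward merge height (Å)")
    _save(fig, "E_dendrogram.png")

    # F: representative quality scores
    fig, ax = plt.subplots(figsize=(4, 3.5))
    ks = sorted(c.quality_scores)
    ax.bar([f"cluster {i}\n(model {c.representatives[i]})" for i in ks],
           [c.quality_scores[i] for i in ks], color="goldenrod")
    ax.set_ylim(0, 1.05); ax.set_ylabel("composite quality score")
    _save(fig, "F_representative_quality.png")

    # G: cluster diversity metrics
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ks = sorted(c.diversity)
    width = 0.27
    xs = np.arange(len(ks))
    ax.bar(xs - width, [c.diversity[i]["mean_intra_rmsd"] for i in ks], width,
           label="mean intra-RMSD")
    ax.bar(xs, [c.diversity[i]["diameter"] for i in ks], width, label="diameter",
           color="crimson")
    ax.bar(xs + width, [5 * c.diversity[i]["compactness"] for i in ks], width,
           label="compactness x 5", color="seagreen")
    ax.set_xticks(xs, [f"cluster {i}" for i in ks]); ax.legend(fontsize=7)
    _save(fig, "G_cluster_diversity.png")

    # H: radius of gyration per model
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.bar([str(m) for m in models], report.flexibility.rg_per_model,
           color=[f"C{l}" for l in c.labels])
    for i, m in enumerate(models):
        if m in rep_ids:
            ax.plot(i, report.flexibility.rg_per_model[i] + 0.1, "*", color="gold",
                    markersize=12)
    ax.set_xlabel("model"); ax.set_ylabel("Rg (Å)")
    _save(fig, "H_radius_of_gyration.png")

    # I: per-residue RMSF
    fig, ax = plt.subplots(figsize=(6, 3.5))
    rmsf = report.flexibility.rmsf_per_residue
    xs = np.arange(len(rmsf))
    ax.plot(xs, rmsf, "-", lw=1)
    thr = np.percentile(rmsf, 75)
    ax.plot(xs[rmsf > thr], rmsf[rmsf > thr], "r.", label="> 75th percentile")
    ax.axhline(report.flexibility.rmsf_mean, color="red", linestyle="--",
               label=f"mean {report.flexibility.rmsf_mean:.2f} Å")
    ax.set_xlabel("residue"); ax.set_ylabel("RMSF (Å)"); ax.legend(fontsize=7)
    _save(fig, "I_per_residue_rmsf.png")
    return written
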
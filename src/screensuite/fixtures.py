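"""Synthetic inputs with planted ground truth.

Three generators emulate the inputs of the other modules so every stage is
testable without any download:

* :func:`make_two_state_ensemble` — a multi-model backbone-only PDB whose
  models fall into clusters with chosen occupancies, separated by an
  internal (alignment-proof) hinge deformation, plus optional strongly
  displaced outlier models and isotropic Gaussian coordinate noise. The
  default parameters emulate a 15-model two-state NMR bundle with a
  dominant (~87 %) and a minor (~13 %) conformational state.
* :func:`make_score_table` — a bivariate-normal (docking score, MM-GBSA
  ΔG_bind) table with requested means, SDs and Pearson correlation, and an
  exactly planted dual-cutoff pass fraction.
* :func:`make_smiles_fixture` — SMILES tables whose rows are planted to
  pass every filter, fail one specific stage, be malformed, or duplicate an
  earlier passer.

The synthetic "proteins" are geometric backbones (ideal-offset polylines),
not physically valid structures; that is sufficient for superposition,
RMSD and clustering math. All generators are byte-deterministic for a
fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EnsembleSpec",
    "ScoreTableSpec",
    "make_two_state_ensemble",
    "make_score_table",
    "make_smiles_fixture",
    "SMILES_POOLS",
]


# ---------------------------------------------------------------------------
# two-state conformer ensemble
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnsembleSpec:
    """Parameters of the planted conformer ensemble.

    ``n_models`` includes the outliers; the remaining models are split
    among clusters by ``cluster_occupancies`` (largest-remainder rounding).
    ``inter_cluster_shift`` is the hinge displacement amplitude between
    cluster mean structures, ``noise_sigma`` the isotropic per-coordinate
    Gaussian noise, and ``outlier_shift`` the (much larger) deformation of
    outlier models. All lengths in Angstroms.
    """

    n_models: int = 15
    n_residues: int = 40
    cluster_occupancies: tuple[float, ...] = (0.87, 0.13)
    inter_cluster_shift: float = 6.0
    noise_sigma: float = 0.5
    n_outliers: int = 0
    outlier_shift: float = 50.0
    seed: int = 42

    def __post_init__(self) -> None:
        if abs(sum(self.cluster_occupancies) - 1.0) > 1e-9:
            raise ValueError("cluster occupancies must sum to 1")
        if self.inter_cluster_shift <= 0 or self.noise_sigma < 0:
            raise ValueError("shift must be > 0 and sigma >= 0")
        if self.n_outliers >= self.n_models:
            raise ValueError("outliers must be fewer than models")


_BACKBONE_OFFSETS = {  # idealized local offsets from CA, Angstroms
    "N": np.array([-1.20, 0.60, 0.00]),
    "CA": np.array([0.00, 0.00, 0.00]),
    "C": np.array([1.25, 0.55, 0.00]),
    "O": np.array([1.60, 1.70, 0.30]),
}


def _base_backbone(n_residues: int) -> tuple[np.ndarray, list[tuple[str, int]]]:
    """A smooth helical CA trace decorated with N/CA/C/O offsets."""
    t = np.arange(n_residues, dtype=float)
    ca = np.stack(
        [2.3 * np.cos(0.6 * t), 2.3 * np.sin(0.6 * t), 1.5 * t], axis=1
    )
    coords, labels = [], []
    for i in range(n_residues):
        for name in ("N", "CA", "C", "O"):
            coords.append(ca[i] + _BACKBONE_OFFSETS[name])
            labels.append((name, i + 1))
    return np.array(coords), labels


def _occupancy_counts(fractions: tuple[float, ...], n: int) -> list[int]:
    """Largest-remainder apportionment of n models among clusters."""
    raw = [f * n for f in fractions]
    counts = [int(np.floor(r)) for r in raw]
    remainder = n - sum(counts)
    order = np.argsort([c - r for c, r in zip(counts, raw)])  # biggest deficit first
    for i in range(remainder):
        counts[order[i]] += 1
    return counts


def make_two_state_ensemble(
    spec: EnsembleSpec = EnsembleSpec(),
) -> tuple[str, dict]:
    """Generate a multi-model PDB text with planted cluster structure.

    Cluster c's mean structure displaces the second half of the chain along
    a cluster-specific direction by ``inter_cluster_shift`` with a smooth
    ramp (a hinge motion), so the separation survives rigid superposition.
    Outlier models use the same construction with ``outlier_shift``.

    Returns ``(pdb_text, truth)`` where ``truth`` has keys ``labels``
    (planted cluster per model, -1 for outliers), ``outliers`` (model
    indices, 0-based), ``model_ids`` (1-based, as written to the file).
    """
    rng = np.random.default_rng(spec.seed)
    base, labels = _base_backbone(spec.n_residues)
    n_atoms = base.shape[0]

    # smooth 0->1 ramp over the second half of the atoms: hinge weight
    ramp = np.clip(np.linspace(-1.0, 1.0, n_atoms), 0.0, 1.0)
    directions = [
        np.array([1.0, 0.0, 0.0]),
        np.array([0.0, 1.0, 0.0]),
        np.array([0.0, 0.0, 1.0]),
        np.array([1.0, 1.0, 0.0]) / np.sqrt(2),
    ]

    n_regular = spec.n_models - spec.n_outliers
    counts = _occupancy_counts(spec.cluster_occupancies, n_regular)
    planted: list[int] = []
    means: list[np.ndarray] = []
    for c, count in enumerate(counts):
        direction = directions[c % len(directions)] if c > 0 else np.zeros(3)
        mean_c = base + spec.inter_cluster_shift * ramp[:, None] * direction
        for _ in range(count):
            planted.append(c)
            means.append(mean_c)
    out_dir = directions[(len(counts) + 1) % len(directions)]
    for _ in range(spec.n_outliers):
        planted.append(-1)
        means.append(base + spec.outlier_shift * ramp[:, None] * out_dir)

    models = [
        mean + rng.normal(0.0, spec.noise_sigma, size=(n_atoms, 3))
        for mean in means
    ]
    pdb_text = _write_pdb_models(models, labels)
    truth = {
        "labels": list(planted),
        "outliers": [i for i, c in enumerate(planted) if c == -1],
        "model_ids": list(range(1, spec.n_models + 1)),
        "occupancy_counts": counts,
        "spec": spec,
    }
    return pdb_text, truth


def _write_pdb_models(
    models: list[np.ndarray], labels: list[tuple[str, int]], chain: str = "A"
) -> str:
    lines: list[str] = []
    for m, coords in enumerate(models, start=1):
        lines.append(f"MODEL     {m:>4d}")
        serial = 1
        for (name, resnum), (x, y, z) in zip(labels, coords):
            pad_name = f" {name:<3s}"  # standard left-justified from col 14
            lines.append(
                f"ATOM  {serial:>5d} {pad_name} ALA {chain}{resnum:>4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          "
                f"{name[0]:>2s}"
            )
            serial += 1
        lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# score tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScoreTableSpec:
    """Parameters of the synthetic (gscore, ΔG_bind) table.

    Defaults emulate the reported distribution of a ~9.4k-hit screen:
    gscore mean -6.80 (SD 0.91), ΔG_bind mean -41.47 (SD 9.65) kcal/mol,
    Pearson R 0.363. ``pass_fraction`` plants the exact fraction of rows
    passing the dual cutoff; None leaves the drawn values untouched.
    """

    n: int = 9353
    g_mean: float = -6.80
    g_sd: float = 0.91
    dg_mean: float = -41.47
    dg_sd: float = 9.65
    pearson_r: float = 0.363
    pass_fraction: float | None = None
    g_cut: float = -6.0
    dg_cut: float = -40.0
    seed: int = 42

    def __post_init__(self) -> None:
        if not (-1.0 < self.pearson_r < 1.0):
            raise ValueError("|pearson_r| must be < 1")
        if self.n < 2:
            raise ValueError("n must be >= 2")


def make_score_table(spec: ScoreTableSpec = ScoreTableSpec()) -> tuple[pd.DataFrame, dict]:
    """Draw a correlated bivariate-normal score table.

    When ``pass_fraction`` is set, exactly ``round(pass_fraction * n)`` rows
    pass the dual cutoff: the rows nearest the cutoff boundary (in SD units)
    are nudged minimally across it, so the sample moments stay within
    sampling error of the targets.

    Returns ``(table, truth)``; truth records the planted pass ids/count.
    """
    rng = np.random.default_rng(spec.seed)
    z1 = rng.standard_normal(spec.n)
    z2 = rng.standard_normal(spec.n)
    g = spec.g_mean + spec.g_sd * z1
    dg = spec.dg_mean + spec.dg_sd * (
        spec.pearson_r * z1 + np.sqrt(1 - spec.pearson_r**2) * z2
    )
    if spec.pass_fraction is not None:
        g, dg = _plant_pass_fraction(g, dg, spec)
    table = pd.DataFrame(
        {
            "compound_id": [f"CMPD{i + 1:06d}" for i in range(spec.n)],
            "gscore": g,
            "dg_bind": dg,
        }
    )
    passes = (g <= spec.g_cut) & (dg <= spec.dg_cut)
    truth = {
        "pass_count": int(passes.sum()),
        "pass_fraction": float(passes.mean()),
        "pass_ids": table.loc[passes, "compound_id"].tolist(),
        "spec": spec,
    }
    return table, truth


def _plant_pass_fraction(
    g: np.ndarray, dg: np.ndarray, spec: ScoreTableSpec
) -> tuple[np.ndarray, np.ndarray]:
    g = g.copy()
    dg = dg.copy()
    target = int(round(spec.pass_fraction * spec.n))
    eps_g = 1e-3 * spec.g_sd
    eps_dg = 1e-3 * spec.dg_sd
    passes = (g <= spec.g_cut) & (dg <= spec.dg_cut)
    deficit = target - int(passes.sum())
    if deficit > 0:
        # promote the non-passers needing the smallest move (in SD units)
        cost = np.where(
            passes,
            np.inf,
            np.maximum(0, (g - spec.g_cut) / spec.g_sd)
            + np.maximum(0, (dg - spec.dg_cut) / spec.dg_sd),
        )
        for idx in np.argsort(cost)[:deficit]:
            if g[idx] > spec.g_cut:
                g[idx] = spec.g_cut - eps_g
            if dg[idx] > spec.dg_cut:
                dg[idx] = spec.dg_cut - eps_dg
    elif deficit < 0:
        # demote passers sitting closest to the boundary
        margin = np.where(
            passes,
            np.minimum((spec.g_cut - g) / spec.g_sd, (spec.dg_cut - dg) / spec.dg_sd),
            np.inf,
        )
        for idx in np.argsort(margin)[: -deficit]:
            if (spec.g_cut - g[idx]) / spec.g_sd <= (spec.dg_cut - dg[idx]) / spec.dg_sd:
                g[idx] = spec.g_cut + eps_g
            else:
                dg[idx] = spec.dg_cut + eps_dg
    return g, dg


# ---------------------------------------------------------------------------
# SMILES fixtures
# ---------------------------------------------------------------------------

# Curated pools, verified against RDKit descriptors and the published
# PAINS/BRENK/NIH catalogs. Stage names refer to the ligprep pipeline order.
SMILES_POOLS: dict[str, list[str]] = {
    # pass all filters (distinct canonical structures)
    "pass": [
        "CCO", "CCCO", "CCCCO", "CC(C)O", "CC(C)CO", "CCC(C)O",
        "Cn1cnc2c1c(=O)n(C)c(=O)n2C",        # caffeine
        "CC(=O)NC1CCCCC1",                    # N-cyclohexylacetamide
        "COc1ccccc1", "CCOc1ccccc1", "COc1ccccc1C", "COc1ccc(C)cc1",
        "CC(=O)N(C)C", "CCN(CC)CC(=O)N", "OCC1CCCCC1", "OCCC1CCCCC1",
        "CC1CCCCC1O", "OC1CCCCC1", "CCOC(=O)CC", "CCC(=O)OC",
    ],
    # unparseable rows (rejected at the parse stage)
    "malformed": ["XYZ123", "C1CC", "not_a_smiles", "C(C)(C)(C)(C)C"],
    # breach rule-of-five bounds (first failing stage: lipinski)
    "lipinski": [
        "C" * 40, "C" * 41, "C" * 42, "C" * 43, "C" * 44,  # MW>500, cLogP>5
        "NC(=O)C(N)C(N)C(N)C(N)C(N)C(N)C(=O)N",            # HBD>5
    ],
    # pass lipinski but breach TPSA or rotatable-bond bounds (stage: druglike)
    "druglike": [
        "OCCOCCOCCOCCOCCOCCO",                       # RotB 16
        "COCCOCCOCCOCCOCCOC",                        # RotB 15, methyl-capped
        "CS(=O)(=O)c1cc(S(C)(=O)=O)c(C(N)=O)cc1C(N)=O",  # TPSA 154.5
        "NC(=O)c1cc(S(C)(=O)=O)cc(S(C)(=O)=O)c1C(N)=O",  # TPSA 154.5
    ],
    # match published structural-alert catalogs (stage: alerts)
    "alerts": [
        "S=C1SC(=Cc2ccccc2)C(=O)N1",   # arylidene rhodanine: PAINS ene_rhod_A
        "CC(=O)Cl",                    # acyl halide: BRENK acid_halide
        "O=[N+]([O-])c1ccccc1",        # nitroarene: BRENK nitro_group
    ],
    # permanent net charge; quaternary N also carries a BRENK alert, so under
    # default catalogs these fall at the alerts stage, and at net_charge when
    # catalogs are disabled
    "charged": [
        "C[N+](C)(C)C", "C[N+](C)(C)CCO", "CC[N+](C)(C)CC",
    ],
}


def make_smiles_fixture(
    counts: dict[str, int],
    seed: int = 42,
    alert_catalogs_enabled: bool = True,
) -> tuple[str, pd.DataFrame]:
    """Emit a SMILES CSV with planted per-row verdicts.

    ``counts`` maps category -> number of rows; categories are the keys of
    :data:`SMILES_POOLS` plus ``duplicate`` (copies of already-emitted
    passers, expected to fall at the dedup stage). Failing-category pools
    are cycled when counts exceed the pool size (repeated rejected rows are
    each still logged at their stage); passer counts beyond the pool raise.

    Returns ``(csv_text, truth)`` where truth is a DataFrame with columns
    ``compound_id, smiles, category, expected_stage`` (expected_stage is
    "accepted" for passers).
    """
    rows: list[dict] = []
    idx = 1

    def _emit(smiles: str, category: str, stage: str) -> None:
        nonlocal idx
        rows.append(
            {
                "compound_id": f"MOL{idx:05d}",
                "smiles": smiles,
                "category": category,
                "expected_stage": stage,
            }
        )
        idx += 1

    stage_of = {
        "pass": "accepted",
        "malformed": "parse",
        "lipinski": "lipinski",
        "druglike": "druglike",
        "alerts": "alerts",
        "charged": "alerts" if alert_catalogs_enabled else "net_charge",
    }
    passers_emitted: list[str] = []
    for category, n in counts.items():
        if n <= 0:
            continue
        if category == "duplicate":
            continue  # handled after passers exist
        pool = SMILES_POOLS[category]
        if category == "pass":
            if n > len(pool):
                raise ValueError(
                    f"at most {len(pool)} distinct planted passers available"
                )
            chosen = pool[:n]
            passers_emitted.extend(chosen)
        else:
            chosen = [pool[i % len(pool)] for i in range(n)]
        for smi in chosen:
            _emit(smi, category, stage_of[category])
    n_dup = counts.get("duplicate", 0)
    if n_dup:
        if not passers_emitted:
            raise ValueError("duplicates require at least one planted passer")
        for i in range(n_dup):
            _emit(passers_emitted[i % len(passers_emitted)], "duplicate", "dedup")

    truth = pd.DataFrame(rows)
    if truth.empty:
        warnings.warn("empty SMILES fixture requested")
        return "compound_id,smiles\n", truth
    csv_text = "compound_id,smiles\n" + "".join(
        f"{r['compound_id']},{r['smiles']}\n" for r in rows
    )
    return csv_text, truth


def write_text(text: str, path: str | Path) -> Path:
    """Small helper used by the CLI to persist generated fixtures."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(text)
    return path
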
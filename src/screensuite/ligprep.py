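"""Standardize-and-filter ligand preparation for SMILES libraries.

Raw delimited SMILES tables are turned into screening-ready SDF files:
delimiter sniffing, SMILES parsing, molecular standardization (largest
organic fragment, normalization, charge neutralization, canonical
tautomer), Lipinski rule-of-five and additional drug-likeness filters
(TPSA, rotatable bonds, Fsp3), PAINS/BRENK/NIH structural-alert screening,
net-charge rejection, canonical-SMILES deduplication, and optional 3D
embedding. Each record is rejected at its first failing stage with a
machine-readable reason code, so the input count is always conserved as
accepted + per-stage rejections.

Stage order: parse -> standardize -> lipinski -> druglike -> alerts ->
net_charge -> dedup.
"""

from __future__ import annotations

import csv
import io
import json
import multiprocessing
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem, Crippen, Descriptors, rdMolDescriptors
from rdkit.Chem.FilterCatalog import FilterCatalog, FilterCatalogParams
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

STAGES = ("parse", "standardize", "lipinski", "druglike", "alerts", "net_charge", "dedup")

__all__ = [
    "STAGES",
    "Thresholds",
    "PipelineConfig",
    "LigandRecord",
    "PipelineResult",
    "sniff_delimiter",
    "parse_smiles_table",
    "standardize_molecule",
    "compute_descriptors",
    "lipinski_filter",
    "druglike_filter",
    "structural_alerts",
    "neutral_charge_filter",
    "deduplicate",
    "embed_3d",
    "run_ligprep",
    "records_to_csv",
]


@dataclass(frozen=True)
class Thresholds:
    """Filter cutoffs. Lipinski bounds are the classic rule of five; the
    drug-likeness bounds (TPSA, rotatable bonds, Fsp3) follow common
    screening practice and are fully configurable."""

    mw_max: float = 500.0
    clogp_max: float = 5.0
    hbd_max: int = 5
    hba_max: int = 10
    tpsa_max: float = 140.0
    rotb_max: int = 10
    fsp3_min: float = 0.0  # pass-through unless raised
    lipinski_max_violations: int = 0  # 0 = strict all-four mode; 1 = classic


@dataclass
class PipelineConfig:
    input_path: str = ""
    output_sdf: str = "prepared.sdf"
    log_path: str | None = None
    delimiter: str | None = None  # None = sniff
    id_column: int = 0
    smiles_column: int = 1
    has_header: bool = True
    enable_3d: bool = False
    skip_lipinski: bool = False
    keep_duplicates: bool = False
    alert_catalogs: tuple[str, ...] = ("PAINS", "BRENK", "NIH")
    thresholds: Thresholds = field(default_factory=Thresholds)
    worker_count: int = 1
    seed: int = 42

    def __post_init__(self) -> None:
        if self.worker_count < 1:
            raise ValueError("worker_count must be >= 1")


@dataclass
class LigandRecord:
    compound_id: str
    smiles_raw: str
    smiles_canonical: str | None = None
    descriptors: dict | None = None
    status: str = "accepted"  # accepted | rejected
    stage: str | None = None  # first failing stage when rejected
    reasons: list[str] = field(default_factory=list)
    row: int = -1
    mol: Chem.Mol | None = None


# ---------------------------------------------------------------------------
# table handling
# ---------------------------------------------------------------------------

_CANDIDATE_DELIMITERS = (",", "\t", ";")


def sniff_delimiter(head: str, n_lines: int = 50) -> str:
    """Detect the delimiter (comma, tab or semicolon) of a table head.

    The winner is the candidate giving a consistent column count >= 2 over
    the first ``n_lines`` non-empty lines; comma wins ties.
    """
    lines = [ln for ln in head.splitlines() if ln.strip()][:n_lines]
    if not lines:
        raise ValueError("empty input: cannot sniff delimiter")
    for cand in _CANDIDATE_DELIMITERS:
        counts = {len(ln.split(cand)) for ln in lines}
        if len(counts) == 1 and counts.pop() >= 2:
            return cand
    raise ValueError("no delimiter yields >= 2 consistent columns")


def parse_smiles_table(
    path: str | Path,
    delimiter: str | None = None,
    id_column: int = 0,
    smiles_column: int = 1,
    has_header: bool = True,
) -> tuple[list[LigandRecord], list[LigandRecord]]:
    """Parse a delimited (id, smiles) table.

    Rows whose SMILES fail RDKit parsing are returned in the second list as
    parse-stage rejections (logged, never raised). Returns
    ``(records, rejected)``.
    """
    text = Path(path).read_text()
    if not text.strip():
        warnings.warn(f"{path}: empty input file")
        return [], []
    if delimiter is None:
        delimiter = sniff_delimiter(text)
    reader = csv.reader(io.StringIO(text), delimiter=delimiter)
    rows = list(reader)
    if has_header and rows:
        rows = rows[1:]
    records: list[LigandRecord] = []
    rejected: list[LigandRecord] = []
    for i, row in enumerate(rows):
        if not row or all(not c.strip() for c in row):
            continue
        if len(row) <= max(id_column, smiles_column):
            rejected.append(
                LigandRecord(
                    compound_id=row[0] if row else f"row{i}",
                    smiles_raw=delimiter.join(row),
                    status="rejected", stage="parse",
                    reasons=["missing_column"], row=i,
                )
            )
            continue
        cid = row[id_column].strip()
        smi = row[smiles_column].strip()
        mol = Chem.MolFromSmiles(smi)
        rec = LigandRecord(compound_id=cid, smiles_raw=smi, row=i, mol=mol)
        if mol is None:
            rec.status = "rejected"
            rec.stage = "parse"
            rec.reasons = ["unparseable_smiles"]
            rejected.append(rec)
        else:
            records.append(rec)
    return records, rejected


# ---------------------------------------------------------------------------
# chemistry stages
# ---------------------------------------------------------------------------

_STANDARDIZE_TOOLS: dict | None = None


def _standardize_tools() -> dict:
    # built lazily (and per process) because the objects are not picklable
    global _STANDARDIZE_TOOLS
    if _STANDARDIZE_TOOLS is None:
        _STANDARDIZE_TOOLS = {
            "fragment": rdMolStandardize.LargestFragmentChooser(preferOrganic=True),
            "uncharger": rdMolStandardize.Uncharger(),
            "tautomer": rdMolStandardize.TautomerEnumerator(),
        }
    return _STANDARDIZE_TOOLS


def standardize_molecule(mol: Chem.Mol) -> Chem.Mol:
    """Standardize a molecule: largest organic fragment, normalization,
    charge neutralization, canonical tautomer.

    The output is idempotent: standardizing the result again yields the same
    canonical SMILES. Raises ``ValueError`` on failure (callers convert this
    to a ``standardization_error`` rejection).
    """
    tools = _standardize_tools()
    try:
        m = rdMolStandardize.Cleanup(mol)
        m = tools["fragment"].choose(m)
        m = tools["uncharger"].uncharge(m)
        m = tools["tautomer"].Canonicalize(m)
        Chem.SanitizeMol(m)
    except Exception as exc:  # RDKit raises a zoo of exception types
        raise ValueError(f"standardization failed: {exc}") from exc
    return m


def compute_descriptors(mol: Chem.Mol) -> dict:
    """Physicochemical descriptors used by the filters (SD-tag friendly)."""
    return {
        "MW": round(Descriptors.MolWt(mol), 2),
        "cLogP": round(Crippen.MolLogP(mol), 3),
        "HBD": rdMolDescriptors.CalcNumLipinskiHBD(mol),
        "HBA": rdMolDescriptors.CalcNumLipinskiHBA(mol),
        "TPSA": round(Descriptors.TPSA(mol), 2),
        "RotB": Descriptors.NumRotatableBonds(mol),
        "Fsp3": round(Descriptors.FractionCSP3(mol), 3),
        "NetCharge": Chem.GetFormalCharge(mol),
    }


def lipinski_filter(desc: dict, thresholds: Thresholds = Thresholds()) -> list[str]:
    """Rule-of-five check; returns reason codes (empty list = pass).

    In strict mode (``lipinski_max_violations = 0``) any breached bound
    fails; with 1 the classic "at most one violation" rule applies.
    """
    reasons = []
    if desc["MW"] > thresholds.mw_max:
        reasons.append(f"MW>{thresholds.mw_max:g}")
    if desc["cLogP"] > thresholds.clogp_max:
        reasons.append(f"cLogP>{thresholds.clogp_max:g}")
    if desc["HBD"] > thresholds.hbd_max:
        reasons.append(f"HBD>{thresholds.hbd_max:g}")
    if desc["HBA"] > thresholds.hba_max:
        reasons.append(f"HBA>{thresholds.hba_max:g}")
    if len(reasons) <= thresholds.lipinski_max_violations:
        return []
    return reasons


def druglike_filter(desc: dict, thresholds: Thresholds = Thresholds()) -> list[str]:
    """TPSA / rotatable-bond / Fsp3 drug-likeness check (reason codes)."""
    reasons = []
    if desc["TPSA"] > thresholds.tpsa_max:
        reasons.append(f"TPSA>{thresholds.tpsa_max:g}")
    if desc["RotB"] > thresholds.rotb_max:
        reasons.append(f"RotB>{thresholds.rotb_max:g}")
    if desc["Fsp3"] < thresholds.fsp3_min:
        reasons.append(f"Fsp3<{thresholds.fsp3_min:g}")
    return reasons


_CATALOG_CACHE: dict[tuple[str, ...], FilterCatalog] = {}


def _get_catalog(names: tuple[str, ...]) -> FilterCatalog:
    if names not in _CATALOG_CACHE:
        params = FilterCatalogParams()
        for name in names:
            params.AddCatalog(getattr(FilterCatalogParams.FilterCatalogs, name))
        _CATALOG_CACHE[names] = FilterCatalog(params)
    return _CATALOG_CACHE[names]


def structural_alerts(
    mol: Chem.Mol, catalogs: tuple[str, ...] = ("PAINS", "BRENK", "NIH")
) -> list[str]:
    """Names of matched PAINS/BRENK/NIH substructure alerts (empty = clean)."""
    if not catalogs:
        return []
    cat = _get_catalog(tuple(catalogs))
    return [entry.GetDescription() for entry in cat.GetMatches(mol)]


def neutral_charge_filter(mol: Chem.Mol) -> list[str]:
    """Reject molecules whose net formal charge is nonzero after uncharging.

    Zwitterions with net charge zero pass; permanent ions (e.g. quaternary
    ammonium) fail with reason ``net_charge``.
    """
    return ["net_charge"] if Chem.GetFormalCharge(mol) != 0 else []


def deduplicate(
    records: list[LigandRecord], keep_duplicates: bool = False
) -> tuple[list[LigandRecord], list[LigandRecord]]:
    """Drop later records sharing a canonical SMILES with an earlier one.

    Returns ``(kept, rejected)``; each rejection records the kept compound's
    id in its reason code.
    """
    if keep_duplicates:
        return list(records), []
    seen: dict[str, str] = {}
    kept, rejected = [], []
    for rec in records:
        key = rec.smiles_canonical
        if key in seen:
            rec.status = "rejected"
            rec.stage = "dedup"
            rec.reasons = [f"duplicate_of:{seen[key]}"]
            rejected.append(rec)
        else:
            seen[key] = rec.compound_id
            kept.append(rec)
    return kept, rejected


def embed_3d(mol: Chem.Mol, seed: int = 42) -> Chem.Mol:
    """Add hydrogens and embed one 3D conformer (ETKDGv3), deterministically.

    Raises ``ValueError`` when embedding fails (callers log ``embed_failed``).
    """
    molh = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    if AllChem.EmbedMolecule(molh, params) != 0:
        raise ValueError("embed_failed")
    return molh


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def _process_one(args: tuple[int, str, str, dict]) -> dict:
    """Standardize + filter one molecule. Runs in worker processes; input and
    output are plain picklable types."""
    idx, cid, smiles, cfgd = args
    thresholds = Thresholds(**cfgd["thresholds"])
    out = {"idx": idx, "status": "accepted", "stage": None, "reasons": [],
           "smiles_canonical": None, "descriptors": None, "molblock": None}
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:  # already screened in parse, but workers re-check
        out.update(status="rejected", stage="parse", reasons=["unparseable_smiles"])
        return out
    try:
        mol = standardize_molecule(mol)
    except ValueError:
        out.update(status="rejected", stage="standardize",
                   reasons=["standardization_error"])
        return out
    out["smiles_canonical"] = Chem.MolToSmiles(mol)
    desc = compute_descriptors(mol)
    out["descriptors"] = desc
    if not cfgd["skip_lipinski"]:
        reasons = lipinski_filter(desc, thresholds)
        if reasons:
            out.update(status="rejected", stage="lipinski", reasons=reasons)
            return out
    reasons = druglike_filter(desc, thresholds)
    if reasons:
        out.update(status="rejected", stage="druglike", reasons=reasons)
        return out
    alerts = structural_alerts(mol, tuple(cfgd["alert_catalogs"]))
    if alerts:
        out.update(status="rejected", stage="alerts",
                   reasons=[f"alert:{a}" for a in alerts])
        return out
    reasons = neutral_charge_filter(mol)
    if reasons:
        out.update(status="rejected", stage="net_charge", reasons=reasons)
        return out
    if cfgd["enable_3d"]:
        try:
            mol3d = embed_3d(mol, seed=cfgd["seed"])
            out["molblock"] = Chem.MolToMolBlock(mol3d)
        except ValueError:
            out.update(status="rejected", stage="standardize",
                       reasons=["embed_failed"])
            return out
    else:
        m2d = Chem.Mol(mol)
        AllChem.Compute2DCoords(m2d)
        out["molblock"] = Chem.MolToMolBlock(m2d)
    return out


@dataclass
class PipelineResult:
    accepted: list[LigandRecord]
    rejected: list[LigandRecord]
    counts: dict[str, int]  # per-stage rejection counts + in/accepted
    config: PipelineConfig

    def summary(self) -> dict:
        return {
            "config": {**asdict(self.config)},
            "counts": self.counts,
        }


def run_ligprep(config: PipelineConfig) -> PipelineResult:
    """Run the full preparation pipeline described in the module docstring.

    The output is independent of ``worker_count``: work items carry their
    input index and results are restored to input order before the ordered
    deduplication pass and SDF writing.
    """
    records, parse_rejects = parse_smiles_table(
        config.input_path,
        delimiter=config.delimiter,
        id_column=config.id_column,
        smiles_column=config.smiles_column,
        has_header=config.has_header,
    )
    n_in = len(records) + len(parse_rejects)
    cfgd = {
        "thresholds": asdict(config.thresholds),
        "skip_lipinski": config.skip_lipinski,
        "alert_catalogs": list(config.alert_catalogs),
        "enable_3d": config.enable_3d,
        "seed": config.seed,
    }
    items = [(i, r.compound_id, r.smiles_raw, cfgd) for i, r in enumerate(records)]
    if config.worker_count > 1 and len(items) > 1:
        try:
            ctx = multiprocessing.get_context("fork")
        except ValueError:  # platforms without fork
            ctx = multiprocessing.get_context("spawn")
        with ctx.Pool(config.worker_count) as pool:
            results = pool.map(_process_one, items, chunksize=32)
    else:
        results = [_process_one(it) for it in items]
    results.sort(key=lambda r: r["idx"])  # restore input order

    survivors: list[LigandRecord] = []
    rejected: list[LigandRecord] = list(parse_rejects)
    molblocks: dict[str, str] = {}
    for rec, res in zip(records, results):
        rec.smiles_canonical = res["smiles_canonical"]
        rec.descriptors = res["descriptors"]
        if res["status"] == "rejected":
            rec.status = "rejected"
            rec.stage = res["stage"]
            rec.reasons = res["reasons"]
            rejected.append(rec)
        else:
            molblocks[rec.compound_id] = res["molblock"]
            survivors.append(rec)

    kept, dup_rejects = deduplicate(survivors, keep_duplicates=config.keep_duplicates)
    rejected.extend(dup_rejects)

    counts = {"in": n_in, "accepted": len(kept)}
    for stage in STAGES:
        counts[f"rejected_{stage}"] = sum(1 for r in rejected if r.stage == stage)

    _write_sdf(kept, molblocks, Path(config.output_sdf))
    if config.log_path:
        _write_log(rejected, counts, config, Path(config.log_path))
    return PipelineResult(accepted=kept, rejected=rejected, counts=counts, config=config)


def _write_sdf(records: list[LigandRecord], molblocks: dict[str, str], path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for rec in records:
            block = molblocks[rec.compound_id]
            # name line is the first line of the molblock
            lines = block.split("\n")
            lines[0] = rec.compound_id
            fh.write("\n".join(lines).rstrip("\n") + "\n")
            fh.write(f">  <SMILES>\n{rec.smiles_canonical}\n\n")
            for key, val in (rec.descriptors or {}).items():
                fh.write(f">  <{key}>\n{val}\n\n")
            fh.write("$$$$\n")


def _write_log(
    rejected: list[LigandRecord], counts: dict, config: PipelineConfig, path: Path
) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("# ligprep rejection log\n")
        fh.write("# thresholds: " + json.dumps(asdict(config.thresholds)) + "\n")
        fh.write("# counts: " + json.dumps(counts) + "\n")
        for rec in rejected:
            fh.write(
                f"{rec.row}\t{rec.compound_id}\t{rec.stage}\t{';'.join(rec.reasons)}\n"
            )


def records_to_csv(records: list[LigandRecord], path: str | Path) -> None:
    """Write accepted records back to a (id, smiles) CSV — used to verify that
    re-running the pipeline on its own output is a no-op."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["compound_id", "smiles"])
        for rec in records:
            writer.writerow([rec.compound_id, rec.smiles_canonical])
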
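"""CSV/SDF/SMILES readers and writers for the pipeline's artifacts.

All tabular artifacts are plain CSV with a one-line versioned header
comment (``# ahrqsar/v1 <kind> ...``); readers skip comment lines and
reject unknown major versions.  Site tables carry a mandatory
concentration unit column (``nM`` or ``ng/L``) to prevent silent unit
mistakes — mass concentrations additionally require a molar mass.
"""

from __future__ import annotations

import math
from pathlib import Path

import pandas as pd

from rdkit import Chem
from rdkit import RDLogger

from .curation import ActivityCategory, CurationResult, DoseResponseRecord
from .features import DESCRIPTOR, FINGERPRINT, DescriptorMatrix
from .mixture import BEQResult, REPEntry, SiteSample, ng_per_l_to_nM

__all__ = [
    "SCHEMA_VERSION",
    "read_dose_response_csv",
    "write_dose_response_csv",
    "write_curated_csv",
    "write_ledger_csv",
    "read_descriptor_matrix",
    "write_descriptor_matrix",
    "read_site_table",
    "write_site_table",
    "write_beq_results",
    "write_predictions_csv",
    "read_predictions_csv",
    "read_rep_table",
    "write_rep_table",
    "read_structures",
]

SCHEMA_VERSION = "v1"
_HEADER_PREFIX = "# ahrqsar/"


def _write_header(fh, kind: str, **meta) -> None:
    extras = " ".join(f"{k}={v}" for k, v in meta.items())
    fh.write(f"{_HEADER_PREFIX}{SCHEMA_VERSION} {kind} {extras}".rstrip() + "\n")


def _check_version(path: str | Path) -> None:
    with open(path) as fh:
        first = fh.readline()
    if first.startswith(_HEADER_PREFIX):
        version = first[len(_HEADER_PREFIX):].split()[0]
        major = version.split(".")[0]
        if major != SCHEMA_VERSION:
            raise ValueError(
                f"{path}: unsupported schema version {version!r} (expected {SCHEMA_VERSION})"
            )


def _read_csv(path: str | Path) -> pd.DataFrame:
    _check_version(path)
    return pd.read_csv(path, comment="#")


def _opt(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and not value.strip():
        return None
    return float(value)


def _parse_replicates(cell) -> list[float]:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return []
    text = str(cell).strip()
    if not text:
        return []
    return [float(tok) for tok in text.split(";") if tok.strip()]


def read_dose_response_csv(path: str | Path) -> tuple[list[DoseResponseRecord], pd.DataFrame]:
    """Read raw dose-response records.

    Expected columns: compound_id (or cas/dtxsid as fallback id), purity_pct,
    ec25_ahr_uM, ec20_cyto_uM, replicate_ec25_uM (semicolon-separated),
    is_mixture_or_inorganic, atypical_curve, optional cas / dtxsid / smiles.
    Absent values are empty cells.  Returns the records plus the raw frame
    (for id/smiles carry-through).
    """
    frame = _read_csv(path)
    records = []

    def _cell(row, key) -> str:
        value = row.get(key, "")
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return ""
        return str(value).strip()

    for _, row in frame.iterrows():
        cas = _cell(row, "cas")
        cid = _cell(row, "compound_id") or cas or _cell(row, "dtxsid")
        if not cid:
            raise ValueError(f"{path}: row without any compound identifier")
        records.append(
            DoseResponseRecord(
                compound_id=cid,
                purity_pct=_opt(row.get("purity_pct")),
                ec25_ahr_uM=_opt(row.get("ec25_ahr_uM")),
                ec20_cyto_uM=_opt(row.get("ec20_cyto_uM")),
                is_mixture_or_inorganic=_truthy(row.get("is_mixture_or_inorganic")),
                replicate_ec25_uM=_parse_replicates(row.get("replicate_ec25_uM")),
                has_defined_cas=bool(cas) if "cas" in frame.columns else True,
                atypical_curve=_truthy(row.get("atypical_curve")),
            )
        )
    return records, frame


def _truthy(value) -> bool:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return False
    if isinstance(value, str):
        return value.strip().lower() in ("1", "true", "yes", "y")
    return bool(value)


def write_curated_csv(result: CurationResult, path: str | Path, **meta) -> None:
    frame = result.kept.copy()
    frame["replicate_ec25_uM"] = frame["replicate_ec25_uM"].map(
        lambda reps: ";".join(str(r) for r in reps)
    )
    with open(path, "w") as fh:
        _write_header(fh, "curated", scheme=result.scheme, **meta)
        frame.to_csv(fh, index=False)


def write_ledger_csv(result: CurationResult, path: str | Path, **meta) -> None:
    with open(path, "w") as fh:
        _write_header(fh, "exclusion-ledger", **meta)
        result.ledger_frame().to_csv(fh, index=False)


def read_descriptor_matrix(
    path: str | Path, fingerprint_prefix: str = "FP"
) -> DescriptorMatrix:
    """Read a compounds x predictors table (first column = compound id).

    Columns whose name starts with ``fingerprint_prefix`` are tagged as
    fingerprint bits; everything else is a continuous descriptor.
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    _check_version(path)
    frame = pd.read_csv(path, sep=sep, comment="#", index_col=0)
    frame.index.name = None
    kinds = pd.Series(
        {
            col: FINGERPRINT if col.startswith(fingerprint_prefix) else DESCRIPTOR
            for col in frame.columns
        }
    )
    return DescriptorMatrix(frame, kinds)


def write_descriptor_matrix(matrix: DescriptorMatrix, path: str | Path, **meta) -> None:
    with open(path, "w") as fh:
        _write_header(fh, "descriptor-matrix", **meta)
        matrix.values.rename_axis("compound_id").to_csv(fh)


def read_site_table(path: str | Path) -> list[SiteSample]:
    """Read a long-format site table into per-(site, sampler) samples.

    Required columns: site_id, sampler, compound_id, conc_value,
    conc_unit (nM | ng/L), beq_bio_nM; ng/L rows additionally require
    molar_mass_g_mol.
    """
    frame = _read_csv(path)
    required = {"site_id", "sampler", "compound_id", "conc_value", "conc_unit"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing site-table columns {sorted(missing)}")
    samples = []
    for (site, sampler), group in frame.groupby(["site_id", "sampler"], sort=True):
        conc = {}
        for _, row in group.iterrows():
            unit = str(row["conc_unit"]).strip()
            value = float(row["conc_value"])
            if unit == "nM":
                conc_nM = value
            elif unit == "ng/L":
                mm = _opt(row.get("molar_mass_g_mol"))
                if mm is None:
                    raise ValueError(
                        f"{path}: ng/L row for {row['compound_id']} lacks molar_mass_g_mol"
                    )
                conc_nM = ng_per_l_to_nM(value, mm)
            else:
                raise ValueError(f"{path}: unknown concentration unit {unit!r}")
            conc[str(row["compound_id"])] = conc_nM
        beq_bio = None
        if "beq_bio_nM" in group.columns:
            vals = {v for v in group["beq_bio_nM"] if _opt(v) is not None}
            if len(vals) > 1:
                raise ValueError(f"{path}: inconsistent beq_bio for {site}/{sampler}")
            beq_bio = _opt(next(iter(vals))) if vals else None
        samples.append(
            SiteSample(
                site_id=str(site), sampler=str(sampler),
                concentrations_nM=conc, beq_bio_nM=beq_bio,
            )
        )
    return samples


def write_beq_results(results: list[BEQResult], path: str | Path, **meta) -> None:
    frame = pd.DataFrame(
        [
            {
                "site_id": r.site_id,
                "sampler": r.sampler,
                "scenario": r.scenario,
                "beq_chem_nM": r.beq_chem_nM,
                "explained_pct": r.explained_pct,
                "n_contributing": r.n_contributing,
                "exclusions": ";".join(r.exclusions),
            }
            for r in results
        ]
    )
    with open(path, "w") as fh:
        _write_header(fh, "beq-results", **meta)
        frame.to_csv(fh, index=False)


def write_predictions_csv(results: list, path: str | Path, **meta) -> None:
    """One row per (compound, model): probability per category + call."""
    rows = []
    for r in results:
        row = {"compound_id": r.compound_id, "model_tag": r.model_tag}
        for cat, p in r.probabilities.items():
            row[f"p_{cat.value}"] = p
        row["predicted_category"] = r.predicted_category.value
        rows.append(row)
    with open(path, "w") as fh:
        _write_header(fh, "predictions", **meta)
        pd.DataFrame(rows).to_csv(fh, index=False)


def write_dose_response_csv(
    records: list[DoseResponseRecord], path: str | Path, **meta
) -> None:
    """Write raw records in the dose-response CSV dialect."""
    rows = []
    for rec in records:
        rows.append(
            {
                "compound_id": rec.compound_id,
                "cas": rec.compound_id if rec.has_defined_cas else "",
                "purity_pct": rec.purity_pct,
                "ec25_ahr_uM": rec.ec25_ahr_uM,
                "ec20_cyto_uM": rec.ec20_cyto_uM,
                "replicate_ec25_uM": ";".join(str(r) for r in rec.replicate_ec25_uM),
                "is_mixture_or_inorganic": int(rec.is_mixture_or_inorganic),
                "atypical_curve": int(rec.atypical_curve),
            }
        )
    with open(path, "w") as fh:
        _write_header(fh, "dose-response", **meta)
        pd.DataFrame(rows).to_csv(fh, index=False)


def write_site_table(samples: list[SiteSample], path: str | Path, **meta) -> None:
    rows = []
    for s in samples:
        for cid, conc in s.concentrations_nM.items():
            rows.append(
                {
                    "site_id": s.site_id,
                    "sampler": s.sampler,
                    "compound_id": cid,
                    "conc_value": conc,
                    "conc_unit": "nM",
                    "molar_mass_g_mol": "",
                    "beq_bio_nM": s.beq_bio_nM,
                }
            )
    with open(path, "w") as fh:
        _write_header(fh, "site-table", **meta)
        pd.DataFrame(rows).to_csv(fh, index=False)


def read_predictions_csv(path: str | Path) -> dict:
    """Inverse of :func:`write_predictions_csv`:
    ``{compound_id: {model_tag: PredictionResult}}``."""
    from .model import PredictionResult

    frame = _read_csv(path)
    prob_cols = [c for c in frame.columns if c.startswith("p_")]
    out: dict[str, dict] = {}
    for _, row in frame.iterrows():
        probs = {
            ActivityCategory(col[2:]): float(row[col])
            for col in prob_cols
            if not (isinstance(row[col], float) and math.isnan(row[col]))
        }
        res = PredictionResult(
            compound_id=str(row["compound_id"]),
            model_tag=str(row["model_tag"]),
            probabilities=probs,
            predicted_category=ActivityCategory(row["predicted_category"]),
        )
        out.setdefault(res.compound_id, {})[res.model_tag] = res
    return out


def write_rep_table(reps: list[REPEntry], path: str | Path, **meta) -> None:
    frame = pd.DataFrame(
        [
            {
                "compound_id": e.compound_id,
                "rep": e.rep,
                "source": e.source,
                "basis_ec25_uM": e.basis_ec25_uM,
                "category": e.category.value if e.category else "",
            }
            for e in reps
        ]
    )
    with open(path, "w") as fh:
        _write_header(fh, "rep-table", **meta)
        frame.to_csv(fh, index=False)


def read_rep_table(path: str | Path) -> list[REPEntry]:
    frame = _read_csv(path)
    entries = []
    for _, row in frame.iterrows():
        raw = row.get("category", "")
        if raw is None or (isinstance(raw, float) and math.isnan(raw)):
            raw = ""
        cat = str(raw).strip()
        entries.append(
            REPEntry(
                compound_id=str(row["compound_id"]),
                rep=float(row["rep"]),
                source=str(row["source"]),
                basis_ec25_uM=float(row["basis_ec25_uM"]),
                category=ActivityCategory(cat) if cat else None,
            )
        )
    return entries


def read_structures(path: str | Path) -> tuple[dict, int]:
    """Read structures from an SDF file or a SMILES list.

    SMILES files hold one record per line: ``SMILES [id]``.  Unparseable
    entries are skipped and counted.  Returns ``(smiles_by_id, n_skipped)``
    with the input's id order preserved.  Raises on an empty file.
    """
    path = Path(path)
    out: dict[str, str] = {}
    skipped = 0
    RDLogger.DisableLog("rdApp.*")
    try:
        if path.suffix.lower() == ".sdf":
            supplier = Chem.SDMolSupplier(str(path))
            for i, mol in enumerate(supplier):
                if mol is None:
                    skipped += 1
                    continue
                name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
                out[name.strip() or f"mol{i + 1}"] = Chem.MolToSmiles(mol)
        else:
            for i, line in enumerate(path.read_text().splitlines()):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                smi, name = parts[0], (parts[1] if len(parts) > 1 else f"mol{i + 1}")
                if Chem.MolFromSmiles(smi) is None:
                    skipped += 1
                    continue
                out[name] = smi
    finally:
        RDLogger.EnableLog("rdApp.*")
    if not out and skipped == 0:
        raise ValueError(f"{path}: no structures found")
    if not out:
        raise ValueError(f"{path}: all {skipped} structures unparseable")
    return out, skipped
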
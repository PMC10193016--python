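"""Readers and writers for molecule tables (.smi, CSV, SDF) and assay CSVs.

Malformed entries are collected into a rejects list, never silently
dropped; readers return ``(records, rejects)``.
"""

from __future__ import annotations

import csv
from pathlib import Path

import pandas as pd
from rdkit import Chem

from .chem import InvalidSmilesError, MoleculeRecord, canonicalize_smiles


def _coerce_label(value):
    if value is None or value == "" or (isinstance(value, float) and pd.isna(value)):
        return None
    return int(float(value))


def read_smi(path) -> tuple[list[MoleculeRecord], list[dict]]:
    """Whitespace-separated SMILES [id] file; missing ids become the
    0-based row index."""
    records, rejects = [], []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        smiles, mol_id = parts[0], (parts[1] if len(parts) > 1 else str(i))
        try:
            records.append(MoleculeRecord(id=mol_id,
                                          smiles=canonicalize_smiles(smiles)))
        except InvalidSmilesError as err:
            rejects.append({"row": i, "input": line, "reason": str(err)})
    return records, rejects


def read_molecule_csv(path) -> tuple[list[MoleculeRecord], list[dict]]:
    """CSV with columns id, smiles and optional label/provenance/parent_id."""
    df = pd.read_csv(path, dtype={"id": str})
    if not {"id", "smiles"} <= set(df.columns):
        raise ValueError(f"{path}: molecule CSV needs columns id, smiles")
    records, rejects = [], []
    for i, row in df.iterrows():
        try:
            records.append(MoleculeRecord(
                id=str(row["id"]),
                smiles=canonicalize_smiles(row["smiles"]),
                label=_coerce_label(row.get("label")),
                provenance=str(row.get("provenance", "seed")),
                parent_id=(None if pd.isna(row.get("parent_id", None))
                           else str(row["parent_id"]))))
        except InvalidSmilesError as err:
            rejects.append({"row": int(i), "input": str(row["smiles"]),
                            "reason": str(err)})
    return records, rejects


def read_sdf(path) -> tuple[list[MoleculeRecord], list[dict]]:
    """SDF; the title line names the record (row index when blank)."""
    records, rejects = [], []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            rejects.append({"row": i, "input": "<unparseable SDF entry>",
                            "reason": "RDKit could not parse entry"})
            continue
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        records.append(MoleculeRecord(id=name or str(i),
                                      smiles=Chem.MolToSmiles(mol)))
    return records, rejects


def read_molecule_table(path, fmt: str | None = None):
    """Dispatch on format: smi, csv or sdf (inferred from suffix)."""
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    readers = {"smi": read_smi, "csv": read_molecule_csv, "sdf": read_sdf}
    if fmt not in readers:
        raise ValueError(f"unsupported molecule format: {fmt}")
    return readers[fmt](path)


def write_molecule_csv(records, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "smiles", "label", "provenance", "parent_id"])
        for r in records:
            writer.writerow([r.id, r.smiles,
                             "" if r.label is None else r.label,
                             r.provenance, r.parent_id or ""])


def read_assay_csv(path) -> pd.DataFrame:
    """Assay CSV: compound, form, concentration_um, replicate, rate,
    control_flag (+ optional batch)."""
    df = pd.read_csv(path)
    required = {"compound", "concentration_um", "replicate", "rate",
                "control_flag"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: assay CSV missing columns {sorted(missing)}")
    return df


def write_dataframe(df: pd.DataFrame, path) -> None:
    """Deterministic CSV output (fixed float formatting, no index)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.6g")
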
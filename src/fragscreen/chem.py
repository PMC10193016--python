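"""Molecule canonicalization, physicochemical properties and feature vectors.

A molecule is represented by its canonical SMILES throughout the package.
Feature vectors concatenate a folded Morgan (extended-connectivity,
radius 2) fingerprint, the 166 standard MACCS structural keys, and seven
Z-scored physicochemical properties: LogP, hydrogen-bond donors and
acceptors, molecular weight, topological polar surface area, rotatable
bonds, and ring count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem, DataStructs, RDLogger
from rdkit.Chem import Crippen, Descriptors, Lipinski, MACCSkeys, rdMolDescriptors
from rdkit.Chem import rdFingerprintGenerator
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

PROPERTY_NAMES = ("logp", "hbd", "hba", "mw", "tpsa", "rot_bonds", "n_rings")


@dataclass
class MoleculeRecord:
    """One molecule with identity, label and provenance.

    label: 1 = active (inhibitor), 0 = inactive, None = unknown.
    provenance: "seed", "augmented" or "library". Augmented records carry
    the id of the seed they were grown from in ``parent_id`` and inherit
    its label.
    """

    id: str
    smiles: str
    label: int | None = None
    provenance: str = "seed"
    parent_id: str | None = None
    meta: dict = field(default_factory=dict)


class InvalidSmilesError(ValueError):
    """Raised when a structure string cannot be parsed."""


_LARGEST_FRAGMENT = rdMolStandardize.LargestFragmentChooser()


def mol_from_smiles(smiles: str) -> Chem.Mol:
    """Parse a SMILES string, keeping the largest organic fragment.

    Raises InvalidSmilesError with the offending input if unparseable.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidSmilesError(f"unparseable SMILES: {smiles!r}")
    if len(Chem.GetMolFrags(mol)) > 1:
        mol = _LARGEST_FRAGMENT.choose(mol)
    return mol


def canonicalize_smiles(smiles: str) -> str:
    """Return the toolkit-canonical SMILES; idempotent for valid input."""
    return Chem.MolToSmiles(mol_from_smiles(smiles))


def _as_mol(mol_or_record) -> Chem.Mol:
    if isinstance(mol_or_record, Chem.Mol):
        return mol_or_record
    smiles = mol_or_record.smiles if isinstance(mol_or_record, MoleculeRecord) else mol_or_record
    return mol_from_smiles(smiles)


def compute_properties(mol_or_record) -> dict:
    """Seven physicochemical properties, keyed by PROPERTY_NAMES.

    Units: logp unitless, mw g/mol, tpsa Å², others counts.
    """
    mol = _as_mol(mol_or_record)
    return {
        "logp": float(Crippen.MolLogP(mol)),
        "hbd": int(Lipinski.NumHDonors(mol)),
        "hba": int(Lipinski.NumHAcceptors(mol)),
        "mw": float(Descriptors.MolWt(mol)),
        "tpsa": float(rdMolDescriptors.CalcTPSA(mol)),
        "rot_bonds": int(rdMolDescriptors.CalcNumRotatableBonds(mol)),
        "n_rings": int(rdMolDescriptors.CalcNumRings(mol)),
    }


def property_array(mol_or_record) -> np.ndarray:
    props = compute_properties(mol_or_record)
    return np.array([props[name] for name in PROPERTY_NAMES], dtype=float)


@dataclass
class FeaturizerConfig:
    ecfp_radius: int = 2
    ecfp_bits: int = 2048
    use_maccs: bool = True

    @property
    def n_features(self) -> int:
        return self.ecfp_bits + (166 if self.use_maccs else 0) + len(PROPERTY_NAMES)

    def to_dict(self) -> dict:
        return {"ecfp_radius": self.ecfp_radius, "ecfp_bits": self.ecfp_bits,
                "use_maccs": self.use_maccs}


@dataclass
class ScalerParams:
    """Per-property mean/sd fitted on a training set.

    Columns with sd = 0 are flagged and transform to exactly 0, so a
    constant training column cannot leak spurious variation at predict
    time.
    """

    mean: np.ndarray
    std: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.std = np.asarray(self.std, dtype=float)
        if np.any(self.std < 0):
            raise ValueError("standard deviations must be non-negative")

    @classmethod
    def fit(cls, values: np.ndarray) -> "ScalerParams":
        values = np.asarray(values, dtype=float)
        params = cls(mean=values.mean(axis=0), std=values.std(axis=0))
        if np.any(params.std == 0):
            idx = [PROPERTY_NAMES[i] for i in np.flatnonzero(params.std == 0)]
            warnings.warn(f"constant property column(s) scaled to 0: {idx}")
        return params

    def transform(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        out = np.zeros_like(values)
        ok = self.std > 0
        out[:, ok] = (values[:, ok] - self.mean[ok]) / self.std[ok]
        return out

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "std": self.std.tolist(),
                "properties": list(PROPERTY_NAMES)}

    @classmethod
    def from_dict(cls, d: dict) -> "ScalerParams":
        return cls(mean=np.array(d["mean"]), std=np.array(d["std"]))


def ecfp_fingerprint(mol_or_record, radius: int = 2, n_bits: int = 2048):
    """Folded Morgan fingerprint as an RDKit ExplicitBitVect."""
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    return gen.GetFingerprint(_as_mol(mol_or_record))


def _bitvect_to_array(fp, n_bits: int) -> np.ndarray:
    arr = np.zeros((n_bits,), dtype=np.int32)
    DataStructs.ConvertToNumpyArray(fp, arr)
    return arr


def featurize(records, scaler: ScalerParams | None = None,
              config: FeaturizerConfig | None = None):
    """Feature matrix for a list of molecules.

    Fingerprint blocks stay binary; the 7-property block is Z-scored with
    ``scaler`` (fitted on ``records`` when None — i.e. records is a
    training set). Returns ``(X, scaler)`` with row order preserved.
    """
    if len(records) == 0:
        raise ValueError("cannot featurize an empty molecule list")
    config = config or FeaturizerConfig()
    ecfp_rows, maccs_rows, prop_rows = [], [], []
    for rec in records:
        mol = _as_mol(rec)
        ecfp_rows.append(_bitvect_to_array(
            ecfp_fingerprint(mol, config.ecfp_radius, config.ecfp_bits), config.ecfp_bits))
        if config.use_maccs:
            # MACCS bit 0 is unused padding; keep the 166 real keys
            maccs_rows.append(_bitvect_to_array(MACCSkeys.GenMACCSKeys(mol), 167)[1:])
        prop_rows.append(property_array(mol))
    props = np.array(prop_rows)
    if scaler is None:
        scaler = ScalerParams.fit(props)
    blocks = [np.array(ecfp_rows, dtype=float)]
    if config.use_maccs:
        blocks.append(np.array(maccs_rows, dtype=float))
    blocks.append(scaler.transform(props))
    return np.hstack(blocks), scaler
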
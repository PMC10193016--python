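"""Fragment-growing data augmentation with a conservatism radius.

Each seed molecule is expanded into up to ``k`` structurally conservative
analogs that inherit the seed's activity label. Edits are drawn from a
fragment library built by cutting single acyclic bonds of a reference
compound collection and keying each removed fragment by the canonical
subgraph within ``radius`` bonds of the attachment point. An edit is
admissible at a seed site only when the site's own radius-``radius``
environment matches a library key, which confines every analog's change
to one local site — the structural premise being that in a continuous
structure-activity landscape a small local edit produces a small activity
change, so the seed's label can be propagated to the analog.

Two edit types are produced:

* grow — replace a hydrogen with a library fragment;
* mutate — cut an acyclic single bond and swap the removed fragment for a
  different library fragment with a matching attachment environment.
"""

from __future__ import annotations

import random
import warnings
from collections import defaultdict
from dataclasses import dataclass, field

from rdkit import Chem

from .chem import MoleculeRecord, canonicalize_smiles, mol_from_smiles


@dataclass
class AugmentationConfig:
    k: int = 20                    # analogs requested per seed
    radius: int = 3                # attachment-environment conservatism radius
    max_heavy_atom_delta: int = 8  # cap on heavy-atom count change per edit
    max_fragment_size: int = 8     # heavy-atom cap on removed/inserted fragments
    rng_seed: int = 0
    strict: bool = False           # error instead of warn on analog shortfall

    def __post_init__(self):
        if self.k < 0:
            raise ValueError("k must be >= 0")
        if self.radius < 1:
            raise ValueError("radius must be >= 1")

    def to_dict(self) -> dict:
        return {"k": self.k, "radius": self.radius,
                "max_heavy_atom_delta": self.max_heavy_atom_delta,
                "rng_seed": self.rng_seed, "strict": self.strict}


@dataclass
class FragmentLibrary:
    """Map from attachment-environment key to replacement fragments.

    Keys are canonical SMILES of the radius-r subgraph around an
    attachment point (dummy atom); values are canonical SMILES of
    fragments carrying one open attachment point ``[*]``.
    """

    entries: dict = field(default_factory=dict)
    radius: int = 3
    source: str = ""

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def n_fragments(self) -> int:
        return sum(len(v) for v in self.entries.values())


def _cuttable_bonds(mol: Chem.Mol):
    """Indices of single, acyclic, heavy-atom bonds (the mutation sites)."""
    return [b.GetIdx() for b in mol.GetBonds()
            if b.GetBondType() == Chem.BondType.SINGLE and not b.IsInRing()
            and b.GetBeginAtom().GetAtomicNum() > 1
            and b.GetEndAtom().GetAtomicNum() > 1]


def _cut(mol: Chem.Mol, bond_idx: int):
    """Split on one bond; both pieces carry a ``[*]`` attachment dummy."""
    fragmented = Chem.FragmentOnBonds(mol, [bond_idx], addDummies=True,
                                      dummyLabels=[(0, 0)])
    pieces = Chem.GetMolFrags(fragmented, asMols=True, sanitizeFrags=False)
    if len(pieces) != 2:
        return None
    out = []
    for piece in pieces:
        try:
            Chem.SanitizeMol(piece)
        except Exception:
            return None
        out.append(piece)
    return out


def _environment_key(piece: Chem.Mol, radius: int) -> str:
    """Canonical SMILES of the subgraph within ``radius`` bonds of the dummy."""
    dummy = next(a.GetIdx() for a in piece.GetAtoms() if a.GetAtomicNum() == 0)
    dm = Chem.GetDistanceMatrix(piece, force=True)
    keep = {i for i in range(piece.GetNumAtoms()) if dm[dummy][i] <= radius}
    bonds = [b.GetIdx() for b in piece.GetBonds()
             if b.GetBeginAtomIdx() in keep and b.GetEndAtomIdx() in keep]
    sub = Chem.PathToSubmol(piece, bonds)
    return Chem.MolToSmiles(sub)


def _heavy_atoms(smiles: str) -> int:
    mol = Chem.MolFromSmiles(smiles, sanitize=False)
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 1)


def _attach(core: Chem.Mol, fragment: Chem.Mol) -> str | None:
    """Zip two one-dummy pieces into a molecule; canonical SMILES or None."""
    core = Chem.Mol(core)
    fragment = Chem.Mol(fragment)
    for m in (core, fragment):
        for atom in m.GetAtoms():
            if atom.GetAtomicNum() == 0:
                atom.SetAtomMapNum(1)
                atom.SetIsotope(0)
    try:
        merged = Chem.molzip(Chem.CombineMols(core, fragment))
        Chem.SanitizeMol(merged)
        return Chem.MolToSmiles(merged)
    except Exception:
        return None


def _grow_sites(mol: Chem.Mol):
    """Carbon atoms with a spare hydrogen, returned as one-dummy pieces."""
    sites = []
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() != 6 or atom.GetTotalNumHs() < 1:
            continue
        rw = Chem.RWMol(mol)
        d = rw.AddAtom(Chem.Atom(0))
        rw.AddBond(atom.GetIdx(), d, Chem.BondType.SINGLE)
        piece = rw.GetMol()
        try:
            Chem.SanitizeMol(piece)
        except Exception:
            continue
        sites.append(piece)
    return sites


def build_fragment_library(ref_mols, radius: int = 3,
                           source: str = "") -> FragmentLibrary:
    """Cut every single acyclic bond of every reference molecule.

    Both pieces of each cut are registered: the retained side defines the
    environment key, the removed side joins that key's fragment set.
    """
    if not ref_mols:
        raise ValueError("reference collection is empty")
    entries = defaultdict(set)
    for rec in ref_mols:
        smiles = rec.smiles if isinstance(rec, MoleculeRecord) else rec
        mol = mol_from_smiles(smiles)
        for bond_idx in _cuttable_bonds(mol):
            pieces = _cut(mol, bond_idx)
            if pieces is None:
                continue
            for retained, removed in (pieces, pieces[::-1]):
                key = _environment_key(retained, radius)
                entries[key].add(Chem.MolToSmiles(removed))
    return FragmentLibrary(entries=dict(entries), radius=radius, source=source)


def _enumerate_edits(mol: Chem.Mol, lib: FragmentLibrary, cfg: AugmentationConfig):
    """All admissible (site-piece, fragment-SMILES) edits, in a stable order."""
    edits = []
    for bond_idx in _cuttable_bonds(mol):
        pieces = _cut(mol, bond_idx)
        if pieces is None:
            continue
        for retained, removed in (pieces, pieces[::-1]):
            removed_smiles = Chem.MolToSmiles(removed)
            removed_heavy = _heavy_atoms(removed_smiles)
            # only peripheral fragments are swappable: the retained core
            # must be the bulk of the seed for the edit to be conservative
            if removed_heavy > cfg.max_fragment_size:
                continue
            key = _environment_key(retained, cfg.radius)
            for frag in sorted(lib.entries.get(key, ())):
                if frag == removed_smiles:
                    continue
                if _heavy_atoms(frag) > cfg.max_fragment_size:
                    continue
                if abs(_heavy_atoms(frag) - removed_heavy) > cfg.max_heavy_atom_delta:
                    continue
                edits.append((retained, frag))
    for site in _grow_sites(mol):
        key = _environment_key(site, cfg.radius)
        for frag in sorted(lib.entries.get(key, ())):
            if _heavy_atoms(frag) > min(cfg.max_fragment_size,
                                        cfg.max_heavy_atom_delta):
                continue
            edits.append((site, frag))
    return edits


def candidate_stream(seed: MoleculeRecord, lib: FragmentLibrary,
                     cfg: AugmentationConfig):
    """Yield unique canonical analog SMILES of ``seed`` in a reproducible
    shuffled order (seeded by ``cfg.rng_seed`` and the seed id)."""
    mol = mol_from_smiles(seed.smiles)
    seed_canonical = Chem.MolToSmiles(mol)
    edits = _enumerate_edits(mol, lib, cfg)
    rng = random.Random(f"{cfg.rng_seed}:{seed.id}")
    rng.shuffle(edits)
    seen = {seed_canonical}
    for retained, frag in edits:
        frag_mol = Chem.MolFromSmiles(frag)
        if frag_mol is None:
            continue
        smiles = _attach(retained, frag_mol)
        if smiles is None or smiles in seen:
            continue
        seen.add(smiles)
        yield smiles


def grow_molecule(seed: MoleculeRecord, lib: FragmentLibrary,
                  cfg: AugmentationConfig) -> list[MoleculeRecord]:
    """Up to ``cfg.k`` unique analogs of ``seed`` inheriting its label."""
    analogs = []
    for smiles in candidate_stream(seed, lib, cfg):
        if len(analogs) >= cfg.k:
            break
        analogs.append(MoleculeRecord(
            id=f"{seed.id}_a{len(analogs) + 1}", smiles=smiles,
            label=seed.label, provenance="augmented", parent_id=seed.id))
    if len(analogs) < cfg.k:
        msg = (f"seed {seed.id}: only {len(analogs)} unique analogs exist "
               f"at radius {cfg.radius} (requested {cfg.k})")
        if cfg.strict:
            raise RuntimeError(msg)
        warnings.warn(msg)
    return analogs


def augment_dataset(seeds, lib: FragmentLibrary,
                    cfg: AugmentationConfig) -> list[MoleculeRecord]:
    """Seeds plus up to k analogs per seed, globally deduplicated.

    An analog colliding with another seed or an earlier analog is dropped
    and replaced from the seed's remaining candidates when possible.
    """
    for seed in seeds:
        if seed.label is None:
            raise ValueError(f"seed {seed.id} is unlabeled")
    out = list(seeds)
    taken = {canonicalize_smiles(s.smiles) for s in seeds}
    for seed in seeds:
        n = 0
        for smiles in candidate_stream(seed, lib, cfg):
            if n >= cfg.k:
                break
            if smiles in taken:
                continue
            taken.add(smiles)
            n += 1
            out.append(MoleculeRecord(
                id=f"{seed.id}_a{n}", smiles=smiles, label=seed.label,
                provenance="augmented", parent_id=seed.id))
        if n < cfg.k:
            msg = (f"seed {seed.id}: {n}/{cfg.k} unique analogs after "
                   f"global deduplication")
            if cfg.strict:
                raise RuntimeError(msg)
            warnings.warn(msg)
    return out
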
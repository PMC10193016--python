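"""Synthetic inputs for the whole pipeline: labeled seed sets with a
continuous structure-activity landscape, a fragment reference collection,
a drug-like screening library with planted actives, and noisy
concentration-response tables.

The seed generator decorates a fixed panel of drug-like scaffolds with
common medicinal-chemistry substituents and labels each molecule through a
smooth latent activity: a logistic link over a fixed linear combination of
the seven physicochemical properties plus a per-scaffold offset. Because
the latent is a smooth function of the properties and single fragment
edits move the properties only slightly, small structural changes produce
small activity changes — the low-activity-cliff regime the augmentation
scheme assumes. Synthetic inactives come from the same scaffold/substituent
grammar as the actives, so the two classes are property-matched rather
than trivially separable.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from . import augment
from .chem import MoleculeRecord, mol_from_smiles, property_array

# ---------------------------------------------------------------------------
# Fixed chemistry panel

# Every scaffold is a single or fused ring system with no acyclic bond
# between heavy atoms, so no fragment edit (which only touches acyclic
# bonds) can create or destroy a scaffold match: the per-scaffold activity
# offset is invariant under augmentation, which is what keeps the
# structure-activity landscape continuous.
SCAFFOLDS = [
    ("naphthalene", "c1ccc2ccccc2c1"),
    ("indole", "c1ccc2[nH]ccc2c1"),
    ("quinoline", "c1ccc2ncccc2c1"),
    ("isoquinoline", "c1cc2ccccc2cn1"),
    ("benzimidazole", "c1ccc2[nH]cnc2c1"),
    ("benzofuran", "c1ccc2occc2c1"),
    ("benzothiophene", "c1ccc2sccc2c1"),
    ("coumarin", "O=c1ccc2ccccc2o1"),
    ("chromone", "O=c1ccoc2ccccc12"),
    # statin-like delta-valerolactone so the screening demo carries
    # hydroxylactone chemistry
    ("lactone", "O=C1CCCCO1"),
    ("dihydropyridine", "C1C=CNC=C1"),
    ("benzene", "c1ccccc1"),
]

SUBSTITUENTS = [
    "[*]C", "[*]CC", "[*]C(C)C", "[*]C(C)(C)C", "[*]F", "[*]Cl", "[*]Br",
    "[*]O", "[*]OC", "[*]OCC", "[*]N", "[*]N(C)C", "[*]C#N", "[*]C(F)(F)F",
    "[*]C(=O)O", "[*]C(=O)OC", "[*]C(=O)C", "[*]C(=O)N", "[*]S(C)(=O)=O",
    "[*]c1ccccc1", "[*]Cc1ccccc1", "[*]OCc1ccccc1", "[*]c1ccncc1",
    "[*]N1CCOCC1", "[*]N1CCCCC1", "[*]C1CC1", "[*]CCO", "[*]OC(F)(F)F",
    "[*]S(=O)(=O)c1ccccc1", "[*]C(=O)c1ccccc1", "[*]CN1CCOCC1",
]

# Latent activity model: logistic link over standardized properties plus a
# scaffold offset. Standardization constants are fixed descriptors of this
# scaffold/substituent grammar's typical chemistry, so activity is a pure
# function of structure, independent of any sampled dataset.
_PROP_CENTER = np.array([2.9, 0.8, 3.0, 275.0, 49.0, 2.9, 2.5])
_PROP_SCALE = np.array([1.4, 0.8, 1.8, 86.0, 29.0, 1.8, 0.85])
# weights over (logp, hbd, hba, mw, tpsa, rot_bonds, n_rings); the gain is
# deliberately gentle so one substituent edit moves the latent only a
# little, while scaffold offsets carry most of the between-molecule spread
# (single acyclic-bond edits never change the scaffold)
_ACTIVITY_WEIGHTS = np.array([0.9, -0.4, 0.2, 0.6, -0.7, 0.3, 0.5])
_SCAFFOLD_OFFSETS = dict(zip(
    (name for name, _ in SCAFFOLDS),
    (1.6, 1.2, 0.8, 0.7, -0.7, 1.0, 1.4, -1.0, -1.6, 2.2, 1.9, -1.2),
))
_ACTIVITY_GAIN = 0.25
LABEL_THRESHOLD = 0.5

# most-specific scaffold first: a benzene query would otherwise shadow
# every fused/linked ring system that embeds it
_SCAFFOLD_QUERIES = sorted(
    ((name, Chem.MolFromSmiles(smi)) for name, smi in SCAFFOLDS),
    key=lambda pair: -pair[1].GetNumAtoms())


def latent_activity(smiles: str) -> float:
    """Smooth latent activity in (0, 1) for any valid molecule."""
    mol = mol_from_smiles(smiles)
    z = (property_array(mol) - _PROP_CENTER) / _PROP_SCALE
    offset = 0.0
    for name, query in _SCAFFOLD_QUERIES:
        if mol.HasSubstructMatch(query):
            offset = _SCAFFOLD_OFFSETS[name]
            break
    x = _ACTIVITY_GAIN * float(_ACTIVITY_WEIGHTS @ z) + offset
    return 1.0 / (1.0 + math.exp(-x))


@dataclass
class SARGeneratorConfig:
    n_active: int = 68
    n_inactive: int = 37
    min_substituents: int = 2
    max_substituents: int = 3
    label_threshold: float = LABEL_THRESHOLD
    flip_probability: float = 0.02  # label noise; kept well below cliff regime
    rng_seed: int = 0

    def __post_init__(self):
        if not 0 <= self.flip_probability < 0.1:
            raise ValueError("flip probability must stay below 0.1 "
                             "(continuous-SAR regime)")


def _attach_substituent(mol: Chem.Mol, rng: random.Random,
                        substituents=SUBSTITUENTS) -> Chem.Mol | None:
    """Replace one hydrogen on a random carbon with a random substituent."""
    sites = [a.GetIdx() for a in mol.GetAtoms()
             if a.GetAtomicNum() == 6 and a.GetTotalNumHs() >= 1]
    if not sites:
        return None
    idx = rng.choice(sites)
    rw = Chem.RWMol(mol)
    d = rw.AddAtom(Chem.Atom(0))
    rw.AddBond(idx, d, Chem.BondType.SINGLE)
    piece = rw.GetMol()
    try:
        Chem.SanitizeMol(piece)
    except Exception:
        return None
    frag = Chem.MolFromSmiles(rng.choice(substituents))
    smiles = augment._attach(piece, frag)
    return Chem.MolFromSmiles(smiles) if smiles else None


def _random_molecule(rng: random.Random, min_sub: int, max_sub: int) -> str | None:
    _, scaffold_smiles = SCAFFOLDS[rng.randrange(len(SCAFFOLDS))]
    mol = Chem.MolFromSmiles(scaffold_smiles)
    for _ in range(rng.randint(min_sub, max_sub)):
        grown = _attach_substituent(mol, rng)
        if grown is not None:
            mol = grown
    return Chem.MolToSmiles(mol)


def generate_sar_dataset(cfg: SARGeneratorConfig) -> list[MoleculeRecord]:
    """Labeled seed set with the requested per-class counts.

    Latent activity is stored in ``meta["latent"]`` for diagnostics; the
    label is latent >= threshold, flipped with ``flip_probability``.
    """
    rng = random.Random(cfg.rng_seed)
    actives, inactives, seen = [], [], set()
    max_tries = 400 * (cfg.n_active + cfg.n_inactive)
    for _ in range(max_tries):
        if len(actives) >= cfg.n_active and len(inactives) >= cfg.n_inactive:
            break
        smiles = _random_molecule(rng, cfg.min_substituents, cfg.max_substituents)
        if smiles is None or smiles in seen:
            continue
        seen.add(smiles)
        latent = latent_activity(smiles)
        label = int(latent >= cfg.label_threshold)
        if rng.random() < cfg.flip_probability:
            label = 1 - label
        pool = actives if label == 1 else inactives
        want = cfg.n_active if label == 1 else cfg.n_inactive
        if len(pool) < want:
            pool.append((smiles, latent, label))
    if len(actives) < cfg.n_active or len(inactives) < cfg.n_inactive:
        raise RuntimeError(
            f"scaffold panel exhausted: got {len(actives)} active / "
            f"{len(inactives)} inactive of {cfg.n_active}/{cfg.n_inactive}")
    records = []
    for cls, pool in (("act", actives), ("inact", inactives)):
        for i, (smiles, latent, label) in enumerate(pool, start=1):
            records.append(MoleculeRecord(
                id=f"{cls}_{i:03d}", smiles=smiles, label=label,
                provenance="seed", meta={"latent": latent}))
    return records


# ---------------------------------------------------------------------------
# Fragment reference collection (stands in for a public fragment dataset)

_REFERENCE_SEED = 987654321  # part of the collection's definition
_reference_cache: list | None = None
_library_cache: dict = {}


def builtin_fragment_reference(n: int = 800) -> list[MoleculeRecord]:
    """Deterministic built-in drug-like reference collection.

    Drawn from the same scaffold/substituent grammar as the seed
    generator (1-4 substituents) so seed attachment environments are
    densely covered at the default conservatism radius.
    """
    global _reference_cache
    if _reference_cache is not None and len(_reference_cache) == n:
        return _reference_cache
    rng = random.Random(_REFERENCE_SEED)
    seen, records = set(), []
    while len(records) < n:
        smiles = _random_molecule(rng, 1, 4)
        if smiles is None or smiles in seen:
            continue
        seen.add(smiles)
        records.append(MoleculeRecord(id=f"ref_{len(records) + 1:03d}",
                                      smiles=smiles, provenance="library"))
    _reference_cache = records
    return records


def builtin_fragment_library(radius: int = 3) -> augment.FragmentLibrary:
    if radius not in _library_cache:
        _library_cache[radius] = augment.build_fragment_library(
            builtin_fragment_reference(), radius=radius, source="builtin")
    return _library_cache[radius]


# ---------------------------------------------------------------------------
# Screening library

def generate_screening_library(n: int, rng_seed: int,
                               actives: list[MoleculeRecord] | None = None,
                               planted_fraction: float = 0.1):
    """Unlabeled drug-like library of ``n`` molecules with planted positives.

    When ``actives`` is given, about ``planted_fraction`` of the library
    are single-edit analogs of those actives (ground truth for retrieval
    tests). Returns ``(records, planted_ids)``.
    """
    if n < 10:
        raise ValueError("library size must be >= 10")
    rng = random.Random(rng_seed)
    records, planted_ids, seen = [], [], set()
    if actives:
        seen.update(a.smiles for a in actives)
    n_planted = int(round(n * planted_fraction)) if actives else 0
    if n_planted:
        lib = builtin_fragment_library()
        cfg = augment.AugmentationConfig(k=3, rng_seed=rng_seed)
        pool = []
        for seed_rec in actives:
            for smiles in augment.candidate_stream(seed_rec, lib, cfg):
                if smiles not in seen:
                    pool.append(smiles)
                    seen.add(smiles)
                if len(pool) >= 4 * n_planted:
                    break
            if len(pool) >= 4 * n_planted:
                break
        rng.shuffle(pool)
        for smiles in pool[:n_planted]:
            rec_id = f"lib_{len(records) + 1:04d}"
            records.append(MoleculeRecord(id=rec_id, smiles=smiles,
                                          provenance="library",
                                          meta={"planted": True}))
            planted_ids.append(rec_id)
    tries = 0
    while len(records) < n and tries < 400 * n:
        tries += 1
        smiles = _random_molecule(rng, 2, 4)
        if smiles is None or smiles in seen:
            continue
        seen.add(smiles)
        records.append(MoleculeRecord(id=f"lib_{len(records) + 1:04d}",
                                      smiles=smiles, provenance="library"))
    if len(records) < n:
        raise RuntimeError("could not generate the requested library size")
    return records, planted_ids


# ---------------------------------------------------------------------------
# Concentration-response assay generator

#: ten-point concentration ladder used throughout (μM)
CONCENTRATION_LADDER = (0.1, 0.25, 0.5, 1.0, 2.5, 5.0, 10.0, 25.0, 50.0, 100.0)


@dataclass
class AssayGeneratorConfig:
    min_resp: float = 40.0       # lower asymptote, % of negative control
    max_resp: float = 100.0      # upper asymptote, % of negative control
    ic50: float = 10.0           # μM
    hill: float = 1.0
    ladder: tuple = CONCENTRATION_LADDER
    n_reps: int = 3
    noise_sd: float = 5.0        # percentage points
    base_rate: float = 1.0       # negative-control rate, μmol/min/mg
    compound: str = "synthetic"
    form: str = "lactone"
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def four_pl(x, min_resp, max_resp, ic50, hill):
    """Inhibitor concentration vs normalized response:

        Y = Min + (Max - Min) / (1 + (X / IC50)^Hill)

    so activity falls from Max (untreated) to Min (full effect) with a
    positive Hill slope. This is the same curve as the
    ``(IC50/X)^HillSlope`` form with a negative slope, rewritten so the
    slope parameter stays positive for inhibition.
    """
    x = np.asarray(x, dtype=float)
    return min_resp + (max_resp - min_resp) / (1.0 + (x / ic50) ** hill)


def generate_dose_response(cfg: AssayGeneratorConfig):
    """Plate-style raw-rate table: treated wells at each ladder
    concentration plus negative-control wells, with Gaussian noise of
    ``noise_sd`` percentage points on the percent-of-control scale."""
    import pandas as pd

    rng = np.random.default_rng(cfg.rng_seed)
    rows = []
    for rep in range(1, cfg.n_reps + 1):
        noise = rng.normal(0.0, cfg.noise_sd) if cfg.noise_sd else 0.0
        rows.append({"compound": "control", "form": "none",
                     "concentration_um": 0.0, "replicate": rep,
                     "rate": cfg.base_rate * (100.0 + noise) / 100.0,
                     "control_flag": "negative"})
    for conc in cfg.ladder:
        y = float(four_pl(conc, cfg.min_resp, cfg.max_resp, cfg.ic50, cfg.hill))
        for rep in range(1, cfg.n_reps + 1):
            noise = rng.normal(0.0, cfg.noise_sd) if cfg.noise_sd else 0.0
            rows.append({"compound": cfg.compound, "form": cfg.form,
                         "concentration_um": conc, "replicate": rep,
                         "rate": cfg.base_rate * (y + noise) / 100.0,
                         "control_flag": "treated"})
    return pd.DataFrame(rows)


def single_edit_latent_deltas(n_pairs: int, rng_seed: int) -> np.ndarray:
    """|Δ latent activity| for random (molecule, single-edit analog) pairs.

    Diagnostic for the continuous-SAR premise: the distribution should be
    concentrated near zero (few activity cliffs).
    """
    rng = random.Random(rng_seed)
    lib = builtin_fragment_library()
    cfg = augment.AugmentationConfig(k=1, rng_seed=rng_seed)
    deltas = []
    tries = 0
    while len(deltas) < n_pairs and tries < 50 * n_pairs:
        tries += 1
        smiles = _random_molecule(rng, 1, 3)
        if smiles is None:
            continue
        rec = MoleculeRecord(id=f"pair_{tries}", smiles=smiles)
        analog = next(iter(augment.candidate_stream(rec, lib, cfg)), None)
        if analog is None:
            continue
        deltas.append(abs(latent_activity(analog) - latent_activity(smiles)))
    return np.array(deltas)
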
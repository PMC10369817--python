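"""Random-forest comparator: ECFP4 regression with atom-masking attribution.

The attribution follows the perturbation recipe for fingerprint models: each
atom in turn is replaced by a sentinel atom type never seen in drug-like
training chemistry (xenon), the fingerprint recomputed, and the score taken as
the drop in predicted potency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, rdFingerprintGenerator
from sklearn.ensemble import RandomForestRegressor

from .attribution import Attribution
from .chem import Molecule, ecfp4
from .pairing import ActivityRecord

logger = logging.getLogger("ucnbench")

SENTINEL_ATOMIC_NUM = 54  # xenon: absent from the benchmark chemistry


@dataclass
class RFModel:
    forest: RandomForestRegressor
    n_trees: int
    n_bits: int
    radius: int
    seed: int


def _fingerprint_matrix(records: Sequence[ActivityRecord], n_bits: int, radius: int) -> np.ndarray:
    return np.stack([ecfp4(r.molecule, n_bits, radius).bits for r in records]).astype(np.float64)


def rf_train(
    records: Sequence[ActivityRecord],
    n_trees: int = 500,
    seed: int = 0,
    n_bits: int = 2048,
    radius: int = 2,
) -> RFModel:
    """Fit a regression forest on ECFP4 bits -> pIC50."""
    if len(records) < 10:
        raise ValueError(f"need at least 10 records to fit a forest, got {len(records)}")
    y = np.asarray([r.activity for r in records])
    if np.ptp(y) == 0:
        logger.warning("rf_train: constant labels; the forest will predict a constant")
    X = _fingerprint_matrix(records, n_bits, radius)
    forest = RandomForestRegressor(n_estimators=n_trees, random_state=seed, n_jobs=1)
    forest.fit(X, y)
    return RFModel(forest=forest, n_trees=n_trees, n_bits=n_bits, radius=radius, seed=seed)


def rf_predict(model: RFModel, mol: Molecule) -> float:
    fp = ecfp4(mol, model.n_bits, model.radius).bits.astype(np.float64)
    return float(model.forest.predict(fp[None, :])[0])


def _sentinel_variant(mol: Molecule, atom_idx: int) -> Optional[Chem.Mol]:
    """Replace one atom by the sentinel type; None if the variant is unusable."""
    rw = Chem.RWMol(mol.rdmol)
    try:
        Chem.Kekulize(rw, clearAromaticFlags=True)
        atom = rw.GetAtomWithIdx(atom_idx)
        atom.SetAtomicNum(SENTINEL_ATOMIC_NUM)
        atom.SetNoImplicit(True)
        atom.SetNumExplicitHs(0)
        atom.SetFormalCharge(0)
        variant = rw.GetMol()
        Chem.SanitizeMol(variant)
        return variant
    except Exception:  # pragma: no cover - depends on exotic chemistry
        return None


def rf_atom_masking(model: RFModel, mol: Molecule, compound_id: str = "") -> Attribution:
    """score_v = predict(original) - predict(atom v replaced by the sentinel).

    If the sentinel substitution cannot be sanitised, the score falls back to
    dropping the fingerprint bits whose environments contain atom v (logged).
    """
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=model.radius, fpSize=model.n_bits)
    base_fp = ecfp4(mol, model.n_bits, model.radius).bits.astype(np.float64)
    base_pred = float(model.forest.predict(base_fp[None, :])[0])
    scores = np.zeros(mol.n_atoms)
    for v in range(mol.n_atoms):
        variant = _sentinel_variant(mol, v)
        if variant is not None:
            bv = gen.GetFingerprint(variant)
            fp = np.zeros(model.n_bits)
            for b in bv.GetOnBits():
                fp[b] = 1.0
        else:
            logger.warning(
                "sentinel substitution failed for atom %d of %s; dropping its environment bits",
                v, mol.smiles,
            )
            fp = _drop_environment_bits(mol, v, model.n_bits, model.radius)
        scores[v] = base_pred - float(model.forest.predict(fp[None, :])[0])
    return Attribution(compound_id, "RFMasking", scores)


def _drop_environment_bits(mol: Molecule, atom_idx: int, n_bits: int, radius: int) -> np.ndarray:
    bit_info: Dict[int, tuple] = {}
    AllChem.GetMorganFingerprintAsBitVect(mol.rdmol, radius, nBits=n_bits, bitInfo=bit_info)
    fp = np.zeros(n_bits)
    for bit, envs in bit_info.items():
        keep = False
        for center, rad in envs:
            atoms = {center}
            if rad > 0:
                bonds = Chem.FindAtomEnvironmentOfRadiusN(mol.rdmol, rad, center)
                for b in bonds:
                    bond = mol.rdmol.GetBondWithIdx(b)
                    atoms.update((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()))
            if atom_idx not in atoms:
                keep = True
                break
        if keep:
            fp[bit] = 1.0
    return fp
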
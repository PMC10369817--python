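"""Molecule parsing, graph featurization, fingerprints, scaffolds and table I/O.

All downstream stages (pairing, GNN featurization, attribution masks) rely on a
single canonical atom ordering per molecule.  :class:`Molecule` therefore always
re-parses its own canonical SMILES, which makes atom indices stable under
parse -> write -> parse round trips.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator
from rdkit.Chem.Scaffolds import MurckoScaffold

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger("ucnbench")

# ---------------------------------------------------------------------------
# feature vocabularies (fixed so feature dimensions are constant per dataset)
# ---------------------------------------------------------------------------

ELEMENT_VOCAB: Tuple[str, ...] = ("C", "N", "O", "S", "F", "Cl", "Br", "I", "P")
MAX_DEGREE = 5  # degrees 0..5 one-hot; heavier coordination is folded into 5

BOND_ORDER_VOCAB = (
    Chem.BondType.SINGLE,
    Chem.BondType.DOUBLE,
    Chem.BondType.TRIPLE,
    Chem.BondType.AROMATIC,
)

NODE_FEATURE_DIM = len(ELEMENT_VOCAB) + 1 + (MAX_DEGREE + 1) + 1 + 1 + 1
EDGE_FEATURE_DIM = len(BOND_ORDER_VOCAB) + 1


class ParseError(ValueError):
    """Raised when a SMILES/SDF record cannot be parsed into a molecule."""


@dataclass(frozen=True)
class AtomInfo:
    element: str
    formal_charge: int
    is_aromatic: bool
    degree: int
    in_ring: bool


@dataclass(frozen=True)
class BondInfo:
    begin: int
    end: int
    order: str
    is_aromatic: bool
    in_ring: bool


class Molecule:
    """A sanitized heavy-atom molecule in canonical atom order.

    Hydrogens are implicit: atom indices refer exclusively to heavy atoms, and
    those indices are the ones used by MCS masks, ground-truth colorings and
    attribution vectors throughout the package.
    """

    __slots__ = ("smiles", "rdmol")

    def __init__(self, smiles: str, rdmol: Chem.Mol):
        self.smiles = smiles
        self.rdmol = rdmol

    @classmethod
    def from_smiles(cls, smiles: str) -> "Molecule":
        if not isinstance(smiles, str) or not smiles.strip():
            raise ParseError("empty SMILES string")
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ParseError(f"unparseable SMILES: {smiles!r}")
        canonical = Chem.MolToSmiles(mol)
        mol = Chem.MolFromSmiles(canonical)
        if mol is None:  # pragma: no cover - canonical SMILES always reparse
            raise ParseError(f"canonical SMILES failed to reparse: {canonical!r}")
        return cls(canonical, mol)

    @classmethod
    def from_rdmol(cls, rdmol: Chem.Mol) -> "Molecule":
        return cls.from_smiles(Chem.MolToSmiles(rdmol))

    # -- basic views --------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return self.rdmol.GetNumAtoms()

    @property
    def n_bonds(self) -> int:
        return self.rdmol.GetNumBonds()

    @property
    def atoms(self) -> List[AtomInfo]:
        out = []
        for a in self.rdmol.GetAtoms():
            out.append(
                AtomInfo(
                    element=a.GetSymbol(),
                    formal_charge=a.GetFormalCharge(),
                    is_aromatic=a.GetIsAromatic(),
                    degree=a.GetDegree(),
                    in_ring=a.IsInRing(),
                )
            )
        return out

    @property
    def bonds(self) -> List[BondInfo]:
        out = []
        for b in self.rdmol.GetBonds():
            out.append(
                BondInfo(
                    begin=b.GetBeginAtomIdx(),
                    end=b.GetEndAtomIdx(),
                    order=str(b.GetBondType()),
                    is_aromatic=b.GetIsAromatic(),
                    in_ring=b.IsInRing(),
                )
            )
        return out

    def __eq__(self, other) -> bool:
        return isinstance(other, Molecule) and self.smiles == other.smiles

    def __hash__(self) -> int:
        return hash(self.smiles)

    def __repr__(self) -> str:
        return f"Molecule({self.smiles!r})"


def parse_molecule(smiles: str) -> Molecule:
    """Parse a SMILES string into a canonical :class:`Molecule`."""
    return Molecule.from_smiles(smiles)


def write_smiles(mol: Molecule) -> str:
    """Canonical SMILES of a molecule (identity for canonical input)."""
    return mol.smiles


# ---------------------------------------------------------------------------
# graph featurization
# ---------------------------------------------------------------------------


@dataclass
class MolecularGraph:
    """Dense feature view of a molecule for the message-passing model.

    ``edge_index`` has shape (2, 2*n_bonds): every bond appears in both
    directions so that message passing is symmetric.  Row ``v`` of
    ``node_features`` corresponds to atom index ``v`` of the source molecule.
    """

    node_features: np.ndarray  # (N, NODE_FEATURE_DIM)
    edge_index: np.ndarray  # (2, 2 * n_bonds), int64
    edge_features: np.ndarray  # (2 * n_bonds, EDGE_FEATURE_DIM)
    smiles: str = ""

    @property
    def n_atoms(self) -> int:
        return self.node_features.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edge_index.shape[1]


def _atom_features(atom: Chem.Atom) -> np.ndarray:
    x = np.zeros(NODE_FEATURE_DIM, dtype=np.float64)
    sym = atom.GetSymbol()
    try:
        x[ELEMENT_VOCAB.index(sym)] = 1.0
    except ValueError:
        x[len(ELEMENT_VOCAB)] = 1.0  # "other" bucket
    off = len(ELEMENT_VOCAB) + 1
    x[off + min(atom.GetDegree(), MAX_DEGREE)] = 1.0
    off += MAX_DEGREE + 1
    x[off] = float(atom.GetFormalCharge())
    x[off + 1] = 1.0 if atom.GetIsAromatic() else 0.0
    x[off + 2] = 1.0 if atom.IsInRing() else 0.0
    return x


def _bond_features(bond: Chem.Bond) -> np.ndarray:
    e = np.zeros(EDGE_FEATURE_DIM, dtype=np.float64)
    try:
        e[BOND_ORDER_VOCAB.index(bond.GetBondType())] = 1.0
    except ValueError:
        pass  # exotic bond order: all-zero order one-hot
    e[len(BOND_ORDER_VOCAB)] = 1.0 if bond.IsInRing() else 0.0
    return e


def featurize(mol: Molecule) -> MolecularGraph:
    """Build the node/edge feature arrays consumed by the GNN."""
    rd = mol.rdmol
    n = rd.GetNumAtoms()
    node = np.zeros((n, NODE_FEATURE_DIM), dtype=np.float64)
    for i, atom in enumerate(rd.GetAtoms()):
        node[i] = _atom_features(atom)
    src, dst, efeat = [], [], []
    for bond in rd.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        f = _bond_features(bond)
        src.extend([i, j])
        dst.extend([j, i])
        efeat.extend([f, f])
    edge_index = np.asarray([src, dst], dtype=np.int64).reshape(2, -1)
    edge_features = (
        np.asarray(efeat, dtype=np.float64)
        if efeat
        else np.zeros((0, EDGE_FEATURE_DIM))
    )
    return MolecularGraph(node, edge_index, edge_features, smiles=mol.smiles)


# ---------------------------------------------------------------------------
# fingerprints and scaffolds
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Fingerprint:
    bits: np.ndarray  # uint8 vector, length n_bits
    radius: int
    n_bits: int


def ecfp4(mol: Molecule, n_bits: int = 2048, radius: int = 2) -> Fingerprint:
    """Extended-connectivity (Morgan) fingerprint; radius 2 == ECFP4."""
    if n_bits < 64:
        raise ValueError("n_bits must be >= 64")
    if radius < 0:
        raise ValueError("radius must be >= 0")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    bv = gen.GetFingerprint(mol.rdmol)
    arr = np.zeros(n_bits, dtype=np.uint8)
    for b in bv.GetOnBits():
        arr[b] = 1
    return Fingerprint(bits=arr, radius=radius, n_bits=n_bits)


def murcko_scaffold(mol: Molecule) -> Optional[Molecule]:
    """Bemis-Murcko scaffold (ring systems plus linkers); ``None`` if acyclic."""
    core = MurckoScaffold.GetScaffoldForMol(mol.rdmol)
    if core is None or core.GetNumAtoms() == 0:
        return None
    return Molecule.from_rdmol(core)


# ---------------------------------------------------------------------------
# table I/O
# ---------------------------------------------------------------------------


def _to_pic50(value: float, activity_is_raw: bool) -> float:
    if activity_is_raw:
        if value <= 0:
            raise ValueError("raw IC50 must be positive (molar units)")
        return -math.log10(value)
    return float(value)


def read_table(
    path,
    format: str = "csv",
    activity_is_raw: bool = False,
    activity_property: Optional[str] = None,
    target_property: str = "target_id",
):
    """Read activity records from a CSV or SDF file.

    CSV requires columns ``smiles``, ``activity`` and ``target_id``
    (``compound_id`` optional).  Raw IC50 values in molar units are converted
    to pIC50 = -log10(IC50) when ``activity_is_raw`` is set.  Rows that fail to
    parse are skipped with a logged warning; the function returns the list of
    surviving records.
    """
    from .pairing import ActivityRecord  # local import to avoid a cycle

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))

    rows: List[Tuple[str, str, float, str]] = []  # (cid, smiles, activity, target)
    if format == "csv":
        df = pd.read_csv(path)
        required = {"smiles", "activity", "target_id"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"missing required columns: {sorted(missing)}")
        has_cid = "compound_id" in df.columns
        for idx, row in df.iterrows():
            cid = str(row["compound_id"]) if has_cid else f"cpd_{idx}"
            rows.append((cid, str(row["smiles"]), row["activity"], str(row["target_id"])))
    elif format == "sdf":
        if activity_property is None:
            raise ValueError("SDF input needs activity_property naming the data field")
        supplier = Chem.SDMolSupplier(str(path))
        for idx, rd in enumerate(supplier):
            if rd is None:
                rows.append((f"cpd_{idx}", "", float("nan"), ""))
                continue
            cid = rd.GetProp("_Name") if rd.HasProp("_Name") and rd.GetProp("_Name") else f"cpd_{idx}"
            act = rd.GetProp(activity_property) if rd.HasProp(activity_property) else float("nan")
            tgt = rd.GetProp(target_property) if rd.HasProp(target_property) else "target_0"
            rows.append((cid, Chem.MolToSmiles(rd), act, tgt))
    else:
        raise ValueError(f"unknown format: {format!r}")

    records = []
    skipped = 0
    for cid, smi, act, tgt in rows:
        try:
            molecule = parse_molecule(smi)
            activity = _to_pic50(float(act), activity_is_raw)
            if not math.isfinite(activity):
                raise ValueError("non-finite activity")
        except (ParseError, ValueError, TypeError) as exc:
            skipped += 1
            logger.warning("skipping record %s: %s", cid, exc)
            continue
        records.append(
            ActivityRecord(compound_id=cid, molecule=molecule, activity=activity, target_id=tgt)
        )
    if skipped:
        logger.warning("read_table: skipped %d unparseable record(s) of %d", skipped, len(rows))
    return records
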
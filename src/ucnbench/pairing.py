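"""Benchmark construction: MCS, compound pairs, ground-truth colors, splits.

A pair of analogs sharing a large maximum common substructure (MCS) and
differing by at least one log unit of potency is an *activity cliff*: the
substituents outside the MCS (the "uncommon atoms") are presumed responsible
for the potency change.  Uncommon atoms of the more potent compound receive a
+1 ground-truth color, those of the less potent one -1, and the shared core 0.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFMCS

from .chem import Molecule, murcko_scaffold

logger = logging.getLogger("ucnbench")


@dataclass(frozen=True)
class ActivityRecord:
    """One compound with a pIC50 label against one target."""

    compound_id: str
    molecule: Molecule
    activity: float  # pIC50, log10 units
    target_id: str


@dataclass(frozen=True)
class MCSResult:
    common_atoms_i: FrozenSet[int]
    common_atoms_j: FrozenSet[int]
    mcs_size: int
    smarts: str = ""
    timed_out: bool = False


@dataclass
class CompoundPair:
    """An ordered activity-cliff pair; ``record_i`` is the more potent compound."""

    pair_id: str
    record_i: ActivityRecord
    record_j: ActivityRecord
    mcs: MCSResult
    uncommon_i: FrozenSet[int]
    uncommon_j: FrozenSet[int]
    delta_activity: float  # y_i - y_j, positive by construction
    mcs_fraction: float
    ground_truth_i: Optional[np.ndarray] = None  # length N_i, values in {-1,0,+1}
    ground_truth_j: Optional[np.ndarray] = None

    @property
    def evaluable(self) -> bool:
        """Both uncommon sets non-empty: required for UCN training and metrics."""
        return len(self.uncommon_i) > 0 and len(self.uncommon_j) > 0

    @property
    def compound_ids(self) -> Tuple[str, str]:
        return (self.record_i.compound_id, self.record_j.compound_id)


@dataclass
class BenchmarkSplit:
    target_id: str
    train_pairs: List[CompoundPair]
    test_pairs: List[CompoundPair]
    train_compounds: FrozenSet[str]
    test_compounds: FrozenSet[str]
    n_dropped_pairs: int = 0  # pairs straddling the compound split


# ---------------------------------------------------------------------------
# MCS
# ---------------------------------------------------------------------------


def compute_mcs(mol_a: Molecule, mol_b: Molecule, timeout_s: float = 10.0) -> MCSResult:
    """Maximum common substructure under element + bond-order matching.

    Ring atoms/bonds may only match ring atoms/bonds, and rings enter the
    common substructure only as complete rings; both constraints keep the
    common part chemically meaningful as a scaffold.  When several embeddings
    of the MCS exist, the lexicographically smallest atom-index match is
    chosen in each molecule so results are deterministic.
    """
    res = rdFMCS.FindMCS(
        [mol_a.rdmol, mol_b.rdmol],
        atomCompare=rdFMCS.AtomCompare.CompareElements,
        bondCompare=rdFMCS.BondCompare.CompareOrder,
        ringMatchesRingOnly=True,
        completeRingsOnly=True,
        timeout=max(1, int(round(timeout_s))),
    )
    if res.numAtoms == 0 or not res.smartsString:
        return MCSResult(frozenset(), frozenset(), 0, "", res.canceled)
    query = Chem.MolFromSmarts(res.smartsString)
    match_a = _canonical_match(mol_a, query)
    match_b = _canonical_match(mol_b, query)
    if match_a is None or match_b is None:  # pragma: no cover - defensive
        return MCSResult(frozenset(), frozenset(), 0, res.smartsString, res.canceled)
    return MCSResult(
        common_atoms_i=frozenset(match_a),
        common_atoms_j=frozenset(match_b),
        mcs_size=res.numAtoms,
        smarts=res.smartsString,
        timed_out=res.canceled,
    )


def _canonical_match(mol: Molecule, query: Chem.Mol) -> Optional[Tuple[int, ...]]:
    matches = mol.rdmol.GetSubstructMatches(query, uniquify=True, maxMatches=10000)
    if not matches:
        return None
    return min(tuple(sorted(m)) for m in matches)


def mcs_fraction(pair_mcs: MCSResult, mol_a: Molecule, mol_b: Molecule) -> float:
    """min(size/N_a, size/N_b): both compounds must be covered at the threshold."""
    if pair_mcs.mcs_size == 0:
        return 0.0
    return min(pair_mcs.mcs_size / mol_a.n_atoms, pair_mcs.mcs_size / mol_b.n_atoms)


# ---------------------------------------------------------------------------
# pair construction
# ---------------------------------------------------------------------------


def assign_ground_truth(pair: CompoundPair) -> CompoundPair:
    """Color uncommon atoms of the more potent compound +1, the other -1."""
    if pair.delta_activity == 0:
        raise ValueError(f"pair {pair.pair_id}: zero activity difference cannot be colored")
    sign = 1.0 if pair.delta_activity > 0 else -1.0
    gt_i = np.zeros(pair.record_i.molecule.n_atoms)
    gt_j = np.zeros(pair.record_j.molecule.n_atoms)
    gt_i[list(pair.uncommon_i)] = sign
    gt_j[list(pair.uncommon_j)] = -sign
    pair.ground_truth_i = gt_i
    pair.ground_truth_j = gt_j
    return pair


def build_pairs(
    records: Sequence[ActivityRecord],
    mcs_threshold: float = 0.5,
    min_delta: float = 1.0,
    timeout_s: float = 10.0,
) -> List[CompoundPair]:
    """All unordered analog pairs passing the MCS and activity-cliff filters.

    A pair qualifies when mcs_fraction >= ``mcs_threshold`` and
    |y_i - y_j| >= ``min_delta`` (both inclusive).  The more potent compound is
    stored first; output order is deterministic (sorted compound ids).
    """
    targets = {r.target_id for r in records}
    if len(targets) > 1:
        raise ValueError(f"records span multiple targets: {sorted(targets)}")
    ordered = sorted(records, key=lambda r: r.compound_id)
    pairs: List[CompoundPair] = []
    n_timeout = 0
    for ra, rb in itertools.combinations(ordered, 2):
        delta = ra.activity - rb.activity
        if abs(delta) < min_delta or delta == 0:
            continue
        mcs = compute_mcs(ra.molecule, rb.molecule, timeout_s=timeout_s)
        if mcs.timed_out:
            n_timeout += 1
            logger.warning("MCS timeout for (%s, %s); pair excluded", ra.compound_id, rb.compound_id)
            continue
        frac = mcs_fraction(mcs, ra.molecule, rb.molecule)
        if frac < mcs_threshold:
            continue
        if delta > 0:
            ri, rj = ra, rb
            common_i, common_j = mcs.common_atoms_i, mcs.common_atoms_j
        else:
            ri, rj = rb, ra
            common_i, common_j = mcs.common_atoms_j, mcs.common_atoms_i
        uncommon_i = frozenset(range(ri.molecule.n_atoms)) - common_i
        uncommon_j = frozenset(range(rj.molecule.n_atoms)) - common_j
        pair = CompoundPair(
            pair_id=f"{ri.target_id}:{ri.compound_id}|{rj.compound_id}",
            record_i=ri,
            record_j=rj,
            mcs=MCSResult(common_i, common_j, mcs.mcs_size, mcs.smarts, mcs.timed_out),
            uncommon_i=uncommon_i,
            uncommon_j=uncommon_j,
            delta_activity=abs(delta),
            mcs_fraction=frac,
        )
        pairs.append(assign_ground_truth(pair))
    if n_timeout:
        logger.warning("build_pairs: %d pair(s) dropped due to MCS timeout", n_timeout)
    return pairs


def count_substitution_sites(pair: CompoundPair) -> Tuple[int, int]:
    """Connected components of the uncommon-atom subgraph in each molecule."""

    def n_components(mol: Molecule, atoms: FrozenSet[int]) -> int:
        if not atoms:
            return 0
        parent = {a: a for a in atoms}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for b in mol.rdmol.GetBonds():
            i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
            if i in atoms and j in atoms:
                parent[find(i)] = find(j)
        return len({find(a) for a in atoms})

    return (
        n_components(pair.record_i.molecule, pair.uncommon_i),
        n_components(pair.record_j.molecule, pair.uncommon_j),
    )


# ---------------------------------------------------------------------------
# splits and target filtering
# ---------------------------------------------------------------------------


def split_pairs(
    pairs: Sequence[CompoundPair], train_frac: float = 0.8, seed: int = 0
) -> BenchmarkSplit:
    """Leakage-free split: compounds are partitioned, pairs follow.

    A pair lands in train iff both compounds are train compounds, in test iff
    both are test; straddling pairs are dropped and counted.  No compound can
    occur in a train pair and a test pair.
    """
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must lie in (0, 1)")
    target_id = pairs[0].record_i.target_id if pairs else ""
    compounds = sorted({cid for p in pairs for cid in p.compound_ids})
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(compounds))
    n_train = int(round(train_frac * len(compounds)))
    train_set = frozenset(compounds[k] for k in perm[:n_train])
    test_set = frozenset(compounds[k] for k in perm[n_train:])
    train_pairs, test_pairs, dropped = [], [], 0
    for p in pairs:
        a, b = p.compound_ids
        if a in train_set and b in train_set:
            train_pairs.append(p)
        elif a in test_set and b in test_set:
            test_pairs.append(p)
        else:
            dropped += 1
    return BenchmarkSplit(
        target_id=target_id,
        train_pairs=train_pairs,
        test_pairs=test_pairs,
        train_compounds=frozenset(c for p in train_pairs for c in p.compound_ids),
        test_compounds=frozenset(c for p in test_pairs for c in p.compound_ids),
        n_dropped_pairs=dropped,
    )


def filter_targets(
    splits: Iterable[BenchmarkSplit], min_train_pairs: int = 50
) -> List[BenchmarkSplit]:
    """Keep only targets with at least ``min_train_pairs`` training pairs."""
    return [s for s in splits if len(s.train_pairs) >= min_train_pairs]


def chemical_diversity(records: Sequence[ActivityRecord]) -> float:
    """Distinct Murcko scaffolds divided by number of compounds.

    Acyclic molecules share a single sentinel "none" scaffold.
    """
    if not records:
        raise ValueError("chemical_diversity needs at least one record")
    scaffolds = set()
    for r in records:
        core = murcko_scaffold(r.molecule)
        scaffolds.add(core.smiles if core is not None else "none")
    return len(scaffolds) / len(records)


# ---------------------------------------------------------------------------
# pair table export
# ---------------------------------------------------------------------------


def pairs_to_frame(pairs: Sequence[CompoundPair]) -> pd.DataFrame:
    """Flat pair table (one row per pair) for CSV export."""
    rows = []
    for p in pairs:
        si, sj = count_substitution_sites(p)
        rows.append(
            {
                "pair_id": p.pair_id,
                "target_id": p.record_i.target_id,
                "compound_i": p.record_i.compound_id,
                "compound_j": p.record_j.compound_id,
                "smiles_i": p.record_i.molecule.smiles,
                "smiles_j": p.record_j.molecule.smiles,
                "activity_i": p.record_i.activity,
                "activity_j": p.record_j.activity,
                "delta_activity": p.delta_activity,
                "mcs_fraction": p.mcs_fraction,
                "sites_i": si,
                "sites_j": sj,
                "common_i": json.dumps(sorted(p.mcs.common_atoms_i)),
                "common_j": json.dumps(sorted(p.mcs.common_atoms_j)),
                "uncommon_i": json.dumps(sorted(p.uncommon_i)),
                "uncommon_j": json.dumps(sorted(p.uncommon_j)),
            }
        )
    return pd.DataFrame(rows)
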
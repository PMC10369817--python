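"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: the MCS oracle is an
exhaustive common-connected-subgraph search over networkx graphs, and the
random-molecule generator builds acyclic molecules atom by atom, where maximum
common subgraph semantics are unambiguous (a connected common subgraph of two
trees is a subtree, so induced and monomorphic matching coincide and
maximising atoms is equivalent to maximising bonds).
"""

from __future__ import annotations

import itertools
from typing import List, Tuple

import networkx as nx
import numpy as np
from rdkit import Chem

# valence budget per element for the random acyclic molecule builder
_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2}


def random_acyclic_molecule(rng: np.random.Generator, n_atoms: int) -> Chem.Mol:
    """Random chemically valid acyclic molecule with ``n_atoms`` heavy atoms."""
    elements = list(_VALENCE)
    while True:
        rw = Chem.RWMol()
        order_budget: List[int] = []
        symbols: List[str] = []
        for i in range(n_atoms):
            sym = elements[rng.integers(len(elements))]
            rw.AddAtom(Chem.Atom(sym))
            symbols.append(sym)
            order_budget.append(_VALENCE[sym])
        ok = True
        for i in range(1, n_atoms):
            # attach to a random earlier atom with remaining valence
            candidates = [j for j in range(i) if order_budget[j] >= 1]
            if not candidates:
                ok = False
                break
            j = int(candidates[rng.integers(len(candidates))])
            use_double = (
                order_budget[j] >= 2 and order_budget[i] >= 2 and rng.random() < 0.2
            )
            bond = Chem.BondType.DOUBLE if use_double else Chem.BondType.SINGLE
            rw.AddBond(i, j, bond)
            dec = 2 if use_double else 1
            order_budget[i] -= dec
            order_budget[j] -= dec
        if not ok:
            continue
        mol = rw.GetMol()
        try:
            Chem.SanitizeMol(mol)
        except Exception:
            continue
        return mol


def _to_nx(mol: Chem.Mol) -> nx.Graph:
    g = nx.Graph()
    for atom in mol.GetAtoms():
        g.add_node(atom.GetIdx(), element=atom.GetSymbol())
    for bond in mol.GetBonds():
        g.add_edge(
            bond.GetBeginAtomIdx(), bond.GetEndAtomIdx(), order=bond.GetBondTypeAsDouble()
        )
    return g


def _connected_subsets(g: nx.Graph) -> List[frozenset]:
    """All connected node subsets (exponential; fine for <= 10 atoms)."""
    found = set()
    frontier = [frozenset([n]) for n in g.nodes]
    found.update(frontier)
    while frontier:
        nxt = set()
        for s in frontier:
            boundary = {m for n in s for m in g.neighbors(n)} - s
            for m in boundary:
                grown = s | {m}
                if grown not in found:
                    found.add(grown)
                    nxt.add(grown)
        frontier = list(nxt)
    return sorted(found, key=len, reverse=True)


def mcs_size_bruteforce(mol_a: Chem.Mol, mol_b: Chem.Mol) -> int:
    """Exhaustive maximum-common-connected-subgraph size (atom count).

    Valid for acyclic molecules, where every connected common subgraph is a
    common subtree and subgraph monomorphism equals induced matching.
    """
    ga, gb = _to_nx(mol_a), _to_nx(mol_b)
    node_match = nx.algorithms.isomorphism.categorical_node_match("element", None)
    edge_match = nx.algorithms.isomorphism.categorical_edge_match("order", None)
    for subset in _connected_subsets(ga):
        sub = ga.subgraph(subset)
        matcher = nx.algorithms.isomorphism.GraphMatcher(
            gb, sub, node_match=node_match, edge_match=edge_match
        )
        if matcher.subgraph_is_monomorphic():
            return len(subset)
    return 0
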
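"""Synthetic congeneric series with planted, additive substituent effects.

Each target is a series built on one scaffold bearing marked attachment
points.  Every compound picks one substituent per site from a library; its
pIC50 is ``base + sum(site weights) + Normal(0, noise_sd)``.  The generator
records, per compound, the canonical atom indices of every substituent and its
weight — the planted ground truth against which pairing and attribution are
evaluated.

The default scaffolds have no automorphism mapping one attachment site onto
another, and the MCS is computed with complete-ring matching, so the pairwise
MCS of two analogs is exactly the scaffold plus, per site, the maximal common
attachment-rooted subtree of the two substituents.  Those overlap sizes are
computed exactly here by brute force on the (small, acyclic) fragments, which
makes truth-table enumeration of qualifying pairs exact rather than
approximate.  The default fragment library is large (18 groups) relative to
the series size, so each (site, substituent) effect is observed only a
handful of times — the low-data regime in which attribution is genuinely
hard, as in real lead-optimization series.
"""

from __future__ import annotations

import ast
import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from rdkit import Chem

from .chem import Molecule, parse_molecule
from .pairing import ActivityRecord

logger = logging.getLogger("ucnbench")

# Asymmetric heteroaromatic scaffolds with three marked attachment points.
DEFAULT_SCAFFOLDS: Tuple[str, ...] = (
    "O=C(N[*:1])c1cc([*:3])c2nc([*:2])sc2c1",
    "O=C(N[*:1])c1ccc(-c2nc([*:2])c([*:3])o2)cc1",
    "O=C(N[*:1])c1ccc2nc([*:2])n([*:3])c2c1",
    "O=C(N[*:1])c1cnc(-c2ccc([*:2])cc2[*:3])nc1",
    "O=C(N[*:1])c1ccc(-n2cc([*:2])c3cc([*:3])ccc32)cc1",
)

# Single heavy-atom substituents with pairwise-distinct elements: no partial
# overlap between different substituents, handy for small exact fixtures.
DEFAULT_FRAGMENTS: Tuple[str, ...] = ("C", "N", "O", "F", "Cl", "Br", "S", "I")

# Substituent vocabulary of the default benchmark: common medicinal-chemistry
# groups (alkyl, halogen, ether, amine, nitrile, CF3, thioether).  The first
# atom of each SMILES is the attachment atom.  Groups may share rooted
# prefixes (e.g. ethyl within propyl); the truth table accounts for that via
# exact rooted-overlap sizes.
DEFAULT_FRAGMENT_LIBRARY: Tuple[str, ...] = (
    "C", "CC", "CCC", "C(C)C", "C(F)(F)F", "CO", "C#N", "CN",
    "O", "OC", "OCC", "N", "NC", "N(C)C", "F", "Cl", "Br", "SC",
)

FragmentLibrary = Dict[int, List[Tuple[str, float]]]


@dataclass
class SeriesSpec:
    scaffold_template: str  # SMILES with [*:1], [*:2], ... dummies
    substituent_library: Union[FragmentLibrary, List[Tuple[str, float]]]
    base_activity: float = 7.0
    noise_sd: float = 0.1
    n_compounds: int = 80
    seed: int = 0
    target_id: str = "target_0"
    activity_band: Tuple[float, float] = (4.0, 10.0)

    def sites(self) -> List[int]:
        scaf = Chem.MolFromSmiles(self.scaffold_template)
        if scaf is None:
            raise ValueError(f"unparseable scaffold template: {self.scaffold_template!r}")
        sites = sorted(
            a.GetAtomMapNum() for a in scaf.GetAtoms() if a.GetAtomicNum() == 0
        )
        if not sites:
            raise ValueError("scaffold template has no [*:n] attachment points")
        return sites

    def library(self) -> FragmentLibrary:
        if isinstance(self.substituent_library, dict):
            return self.substituent_library
        return {s: list(self.substituent_library) for s in self.sites()}


# ---------------------------------------------------------------------------
# molecule assembly
# ---------------------------------------------------------------------------


def attach_substituents(
    scaffold_template: str, fragments: Dict[int, str]
) -> Tuple[Molecule, Dict[int, List[int]], List[int]]:
    """Attach one fragment per marked site; first fragment atom is the bond head.

    Returns the canonical molecule, a map site -> substituent atom indices and
    the scaffold atom indices, all in canonical atom order.
    """
    scaf = Chem.MolFromSmiles(scaffold_template)
    if scaf is None:
        raise ValueError(f"unparseable scaffold template: {scaffold_template!r}")
    rw = Chem.RWMol(scaf)
    dummies = sorted(
        ((a.GetIdx(), a.GetAtomMapNum()) for a in rw.GetAtoms() if a.GetAtomicNum() == 0),
        key=lambda t: -t[0],  # delete high indices first so lower ones stay valid
    )
    for dummy_idx, site in dummies:
        frag_smi = fragments[site]
        frag = Chem.MolFromSmiles(frag_smi)
        if frag is None:
            raise ValueError(f"unparseable fragment {frag_smi!r} for site {site}")
        neighbor = rw.GetAtomWithIdx(dummy_idx).GetNeighbors()[0].GetIdx()
        n0 = rw.GetNumAtoms()
        combo = Chem.RWMol(Chem.CombineMols(rw.GetMol(), frag))
        combo.AddBond(neighbor, n0, Chem.BondType.SINGLE)
        combo.RemoveAtom(dummy_idx)
        for k in range(frag.GetNumAtoms()):
            idx = n0 + k - 1  # removal of dummy_idx (< n0) shifted fragment down
            combo.GetAtomWithIdx(idx).SetIntProp("site", site)
        rw = combo
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    smiles = Chem.MolToSmiles(mol)
    order = ast.literal_eval(mol.GetProp("_smilesAtomOutputOrder"))
    site_atoms: Dict[int, List[int]] = {}
    scaffold_atoms: List[int] = []
    for canonical_pos, orig in enumerate(order):
        atom = mol.GetAtomWithIdx(orig)
        if atom.HasProp("site"):
            site_atoms.setdefault(atom.GetIntProp("site"), []).append(canonical_pos)
        else:
            scaffold_atoms.append(canonical_pos)
    molecule = parse_molecule(smiles)
    return molecule, {s: sorted(v) for s, v in site_atoms.items()}, sorted(scaffold_atoms)


# ---------------------------------------------------------------------------
# series generation
# ---------------------------------------------------------------------------


def generate_series(spec: SeriesSpec):
    """Generate one congeneric series plus its planted truth table.

    Returns ``(records, truth)`` where ``truth`` maps compound_id to a dict
    with per-site atom indices and weights, the scaffold atoms, and the exact
    (noise-free) and observed activities.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    sites = spec.sites()
    library = spec.library()
    for s in sites:
        if s not in library or not library[s]:
            raise ValueError(f"no substituent library for site {s}")
    combos = list(itertools.product(*[range(len(library[s])) for s in sites]))
    if len(combos) < spec.n_compounds:
        raise ValueError(
            f"library supports only {len(combos)} distinct compounds, "
            f"need {spec.n_compounds}"
        )
    chosen = rng.choice(len(combos), size=spec.n_compounds, replace=False)
    noise = rng.normal(0.0, spec.noise_sd, size=spec.n_compounds)

    records: List[ActivityRecord] = []
    truth: Dict[str, dict] = {}
    seen_smiles: Dict[str, str] = {}
    for k, combo_idx in enumerate(chosen):
        combo = combos[combo_idx]
        frag_map = {s: library[s][combo[si]][0] for si, s in enumerate(sites)}
        weights = {s: library[s][combo[si]][1] for si, s in enumerate(sites)}
        try:
            molecule, site_atoms, scaffold_atoms = attach_substituents(
                spec.scaffold_template, frag_map
            )
        except (ValueError, Chem.rdchem.MolSanitizeException) as exc:
            logger.warning("skipping chemically invalid combination %s: %s", frag_map, exc)
            continue
        if molecule.smiles in seen_smiles:
            logger.warning(
                "duplicate molecule %s for %s; skipping", molecule.smiles, frag_map
            )
            continue
        cid = f"{spec.target_id}_c{k:03d}"
        seen_smiles[molecule.smiles] = cid
        true_activity = spec.base_activity + sum(weights.values())
        activity = float(true_activity + noise[k])
        records.append(
            ActivityRecord(
                compound_id=cid, molecule=molecule, activity=activity, target_id=spec.target_id
            )
        )
        truth[cid] = {
            "sites": {
                int(s): {
                    "atom_indices": site_atoms.get(s, []),
                    "fragment": frag_map[s],
                    "weight": float(weights[s]),
                }
                for s in sites
            },
            "scaffold_atoms": scaffold_atoms,
            "true_activity": float(true_activity),
            "activity": activity,
            "smiles": molecule.smiles,
        }
    return records, truth


def _standardised_weights(rng: np.random.Generator, n: int, sd: float) -> List[float]:
    """Uniform draws recentred and rescaled to an exact mean 0 and sd."""
    w = rng.uniform(-1.0, 1.0, size=n)
    w = (w - w.mean()) / w.std()
    return [float(x) for x in w * sd]


_OVERLAP_CACHE: Dict[Tuple[str, str], int] = {}


def rooted_overlap_size(frag_a: str, frag_b: str) -> int:
    """Atoms in the largest common subtree of two fragments rooted at their
    attachment atoms (the first atom of each SMILES), matching elements and
    bond orders.

    This is exactly how far a pairwise MCS can extend into a substitution
    site when the two compounds carry these fragments there: any extension is
    connected through the attachment bond, so it must be attachment-rooted.
    """
    key = (frag_a, frag_b) if frag_a <= frag_b else (frag_b, frag_a)
    if key in _OVERLAP_CACHE:
        return _OVERLAP_CACHE[key]
    ma, mb = Chem.MolFromSmiles(frag_a), Chem.MolFromSmiles(frag_b)
    if ma is None or mb is None:
        raise ValueError(f"unparseable fragment in {key}")

    def match(ai: int, bi: int, from_a: int, from_b: int) -> int:
        a, b = ma.GetAtomWithIdx(ai), mb.GetAtomWithIdx(bi)
        if a.GetSymbol() != b.GetSymbol():
            return 0
        children_a = [n.GetIdx() for n in a.GetNeighbors() if n.GetIdx() != from_a]
        children_b = [n.GetIdx() for n in b.GetNeighbors() if n.GetIdx() != from_b]
        best = 0

        def assign(i: int, remaining: frozenset, acc: int) -> None:
            nonlocal best
            best = max(best, acc)
            if i >= len(children_a):
                return
            assign(i + 1, remaining, acc)  # leave child i unmatched
            for bj in remaining:
                order_a = ma.GetBondBetweenAtoms(ai, children_a[i]).GetBondTypeAsDouble()
                order_b = mb.GetBondBetweenAtoms(bi, bj).GetBondTypeAsDouble()
                if order_a == order_b:
                    sub = match(children_a[i], bj, ai, bi)
                    if sub:
                        assign(i + 1, remaining - {bj}, acc + sub)

        assign(0, frozenset(children_b), 0)
        return 1 + best

    size = match(0, 0, -1, -1)
    _OVERLAP_CACHE[key] = size
    return size


def expected_qualifying_pairs(
    truth: Dict[str, dict], mcs_threshold: float = 0.5, min_delta: float = 1.0
) -> List[Tuple[str, str]]:
    """Enumerate qualifying pairs straight from the planted truth table.

    The planted MCS of two analogs is the scaffold plus, per site, the
    rooted-overlap size of the two fragments (identical fragments overlap
    fully; different ones in their common attachment-rooted subtree).  Valid
    because the scaffolds are asymmetric and ring matching is complete-ring.
    Returns sorted (more_potent_id, less_potent_id) tuples.
    """
    out = []
    for ca, cb in itertools.combinations(sorted(truth), 2):
        ta, tb = truth[ca], truth[cb]
        delta = ta["activity"] - tb["activity"]
        if abs(delta) < min_delta or delta == 0:
            continue
        common = len(ta["scaffold_atoms"])
        for s, sa in ta["sites"].items():
            sb = tb["sites"][s]
            if sa["fragment"] == sb["fragment"]:
                common += len(sa["atom_indices"])
            else:
                common += rooted_overlap_size(sa["fragment"], sb["fragment"])
        na = len(ta["scaffold_atoms"]) + sum(len(v["atom_indices"]) for v in ta["sites"].values())
        nb = len(tb["scaffold_atoms"]) + sum(len(v["atom_indices"]) for v in tb["sites"].values())
        if min(common / na, common / nb) < mcs_threshold:
            continue
        out.append((ca, cb) if delta > 0 else (cb, ca))
    return sorted(out)


def generate_benchmark(
    n_targets: int = 5,
    n_compounds: int = 80,
    noise_sd: float = 0.1,
    seed: int = 0,
    min_qualifying_pairs: Optional[int] = None,
    max_retries: int = 5,
    mcs_threshold: float = 0.5,
    min_delta: float = 1.0,
    weight_sd: float = 0.5,
):
    """Multi-target benchmark dataset with per-target planted truth.

    Per target, substituent weights are drawn uniformly per (site, fragment)
    and then standardised within each site to mean zero and standard
    deviation ``weight_sd``, so every target has the same substituent-effect
    spread (the signal-to-noise ratio of the series does not hinge on a lucky
    draw).  Draws are resampled (bounded retries) until the truth table
    yields at least ``min_qualifying_pairs`` activity-cliff pairs at the MCS
    threshold (default: a quarter of the candidate pairs, capped at 100).
    Returns ``(records, truths, specs)``.
    """
    if n_targets < 1:
        raise ValueError("n_targets must be >= 1")
    if min_qualifying_pairs is None:
        min_qualifying_pairs = min(100, max(10, n_compounds * (n_compounds - 1) // 8))
    master = np.random.default_rng(seed)
    records: List[ActivityRecord] = []
    truths: Dict[str, dict] = {}
    specs: Dict[str, SeriesSpec] = {}
    for t in range(n_targets):
        target_id = f"T{t:02d}"
        scaffold = DEFAULT_SCAFFOLDS[t % len(DEFAULT_SCAFFOLDS)]
        ok = False
        sites = SeriesSpec(scaffold, list(zip(DEFAULT_FRAGMENTS, [0.0] * 8))).sites()
        for attempt in range(max_retries):
            sub_seed = int(master.integers(0, 2**31 - 1))
            rng = np.random.default_rng(sub_seed)
            spec = SeriesSpec(
                scaffold_template=scaffold,
                substituent_library={
                    s: list(zip(DEFAULT_FRAGMENT_LIBRARY,
                                _standardised_weights(rng, len(DEFAULT_FRAGMENT_LIBRARY), weight_sd)))
                    for s in sites
                },
                base_activity=7.0,
                noise_sd=noise_sd,
                n_compounds=n_compounds,
                seed=sub_seed,
                target_id=target_id,
            )
            series_records, truth = generate_series(spec)
            n_qual = len(expected_qualifying_pairs(truth, mcs_threshold, min_delta))
            if n_qual >= min_qualifying_pairs and len(series_records) == n_compounds:
                records.extend(series_records)
                truths[target_id] = truth
                specs[target_id] = spec
                ok = True
                break
            logger.warning(
                "target %s attempt %d: %d qualifying pairs (< %d); resampling weights",
                target_id, attempt, n_qual, min_qualifying_pairs,
            )
        if not ok:
            raise RuntimeError(
                f"could not realise {min_qualifying_pairs} qualifying pairs for "
                f"{target_id} within {max_retries} attempts"
            )
    return records, truths, specs


def records_to_frame(records: Sequence[ActivityRecord]) -> pd.DataFrame:
    """Activity table in the schema consumed by chem.read_table."""
    return pd.DataFrame(
        {
            "compound_id": [r.compound_id for r in records],
            "smiles": [r.molecule.smiles for r in records],
            "activity": [r.activity for r in records],
            "target_id": [r.target_id for r in records],
        }
    )
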
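import itertools

import numpy as np
import pytest

from ucnbench import (
    ActivityRecord,
    build_pairs,
    chemical_diversity,
    compute_mcs,
    count_substitution_sites,
    filter_targets,
    mcs_fraction,
    parse_molecule,
    split_pairs,
)
from ucnbench.pairing import BenchmarkSplit, assign_ground_truth
from ucnbench.synthetic import attach_substituents

from conftest import ONE_SITE_SCAFFOLD


def _record(cid, smiles, activity, target="T"):
    return ActivityRecord(cid, parse_molecule(smiles), activity, target)


def _analog(fragment):
    mol, _, _ = attach_substituents(ONE_SITE_SCAFFOLD, {1: fragment})
    return mol


# ---------------------------------------------------------------------------
# MCS
# ---------------------------------------------------------------------------


def test_mcs_identical_molecules():
    mol = parse_molecule("CCO")
    r = compute_mcs(mol, mol)
    assert r.mcs_size == 3
    assert r.common_atoms_i == r.common_atoms_j == frozenset({0, 1, 2})
    assert mcs_fraction(r, mol, mol) == 1.0


def test_mcs_disjoint_elements():
    r = compute_mcs(parse_molecule("C"), parse_molecule("N"))
    assert r.mcs_size == 0
    assert mcs_fraction(r, parse_molecule("C"), parse_molecule("N")) == 0.0


def test_mcs_toluene_aniline():
    tol, ani = parse_molecule("Cc1ccccc1"), parse_molecule("Nc1ccccc1")
    r = compute_mcs(tol, ani)
    assert r.mcs_size == 6  # the benzene ring
    assert mcs_fraction(r, tol, ani) == pytest.approx(6 / 7)


# ---------------------------------------------------------------------------
# pair construction
# ---------------------------------------------------------------------------


def test_build_pairs_thresholds():
    """Three analogs at (5.0, 6.5, 5.5): only deltas >= 1 survive, inclusive."""
    records = [
        _record("c1", _analog("C").smiles, 5.0),
        _record("c2", _analog("O").smiles, 6.5),
        _record("c3", _analog("Cl").smiles, 5.5),
    ]
    pairs = build_pairs(records, mcs_threshold=0.5, min_delta=1.0)
    got = {frozenset(p.compound_ids): p.delta_activity for p in pairs}
    assert got == {frozenset({"c1", "c2"}): 1.5, frozenset({"c2", "c3"}): 1.0}
    for p in pairs:
        assert p.record_i.activity > p.record_j.activity  # more potent first


def test_build_pairs_excludes_identical_molecules():
    records = [_record("a", "CCO", 5.0), _record("b", "CCO", 7.0)]
    # same molecule: MCS covers everything, uncommon sets empty; pair is kept
    # (delta passes) but flagged non-evaluable
    pairs = build_pairs(records)
    assert len(pairs) == 1
    assert not pairs[0].evaluable
    assert pairs[0].uncommon_i == frozenset()


def test_build_pairs_order_invariance():
    records = [
        _record("c1", _analog("C").smiles, 5.0),
        _record("c2", _analog("O").smiles, 6.5),
        _record("c3", _analog("Br").smiles, 7.6),
    ]
    a = build_pairs(records)
    b = build_pairs(records[::-1])
    assert [p.pair_id for p in a] == [p.pair_id for p in b]


def test_build_pairs_rejects_mixed_targets():
    with pytest.raises(ValueError, match="multiple targets"):
        build_pairs([_record("a", "CCO", 5, "T1"), _record("b", "CCN", 7, "T2")])


def test_pair_partition_invariant():
    records = [
        _record("c1", _analog("C").smiles, 5.0),
        _record("c2", _analog("N(C)C").smiles, 6.7),
    ]
    (pair,) = build_pairs(records)
    for rec, common, uncommon in (
        (pair.record_i, pair.mcs.common_atoms_i, pair.uncommon_i),
        (pair.record_j, pair.mcs.common_atoms_j, pair.uncommon_j),
    ):
        assert common | uncommon == frozenset(range(rec.molecule.n_atoms))
        assert common & uncommon == frozenset()


def test_ground_truth_coloring():
    records = [
        _record("hi", _analog("C").smiles, 7.0),
        _record("lo", _analog("O").smiles, 6.0),
    ]
    (pair,) = build_pairs(records)
    assert pair.record_i.compound_id == "hi"
    assert all(pair.ground_truth_i[v] == 1 for v in pair.uncommon_i)
    assert all(pair.ground_truth_j[v] == -1 for v in pair.uncommon_j)
    assert all(pair.ground_truth_i[v] == 0 for v in pair.mcs.common_atoms_i)


def test_ground_truth_antisymmetry():
    """Reversing which compound is more potent negates every label."""
    a, b = _analog("C").smiles, _analog("O").smiles
    (fwd,) = build_pairs([_record("x", a, 7.0), _record("y", b, 6.0)])
    (rev,) = build_pairs([_record("x", a, 6.0), _record("y", b, 7.0)])
    # x is most potent in fwd, least potent in rev
    gx_fwd = fwd.ground_truth_i  # x on side i
    gx_rev = rev.ground_truth_j  # x on side j
    assert np.array_equal(gx_fwd, -gx_rev)


def test_assign_ground_truth_zero_delta_errors(small_split):
    pair = (small_split.train_pairs + small_split.test_pairs)[0]
    import copy

    broken = copy.copy(pair)
    broken.delta_activity = 0.0
    with pytest.raises(ValueError, match="zero activity difference"):
        assign_ground_truth(broken)


# ---------------------------------------------------------------------------
# substitution sites
# ---------------------------------------------------------------------------


def test_substitution_sites_single():
    (pair,) = build_pairs(
        [_record("a", "Cc1ccccc1", 7.0), _record("b", "Nc1ccccc1", 5.5)]
    )
    assert count_substitution_sites(pair) == (1, 1)


def test_substitution_sites_two_sites():
    # para-disubstituted vs bare benzene-amide core: two separate methyls
    a = "Cc1ccc(C(=O)NCCN)c(C)c1"   # two methyls on separate ring positions
    b = "c1ccc(C(=O)NCCN)cc1"
    ra, rb = _record("a", a, 7.2), _record("b", b, 6.0)
    (pair,) = build_pairs([ra, rb], mcs_threshold=0.5)
    si, sj = count_substitution_sites(pair)
    assert si == 2  # two disconnected methyl sites on the more potent compound
    assert sj == 0


def test_substitution_sites_empty():
    records = [_record("a", "CCO", 5.0), _record("b", "CCO", 7.0)]
    (pair,) = build_pairs(records)
    assert count_substitution_sites(pair) == (0, 0)


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------


def test_split_determinism(small_split, small_series):
    _, records, _ = small_series
    pairs = build_pairs(records)
    again = split_pairs(pairs, train_frac=0.8, seed=3)
    assert [p.pair_id for p in again.train_pairs] == [p.pair_id for p in small_split.train_pairs]
    assert [p.pair_id for p in again.test_pairs] == [p.pair_id for p in small_split.test_pairs]


def test_split_no_leakage_many_seeds(small_series):
    _, records, _ = small_series
    pairs = build_pairs(records)
    for seed in range(50):
        s = split_pairs(pairs, seed=seed)
        assert not (s.train_compounds & s.test_compounds)


def test_split_two_compound_pair_never_straddles():
    records = [_record("a", "Cc1ccccc1", 7.0), _record("b", "Nc1ccccc1", 5.5)]
    pairs = build_pairs(records)
    for seed in range(10):
        s = split_pairs(pairs, train_frac=0.5, seed=seed)
        assert len(s.train_pairs) + len(s.test_pairs) + s.n_dropped_pairs == 1


def test_filter_targets_threshold(small_split):
    def fake(n):
        return BenchmarkSplit(
            target_id=f"t{n}", train_pairs=[small_split.train_pairs[0]] * n,
            test_pairs=[], train_compounds=frozenset(), test_compounds=frozenset(),
        )

    kept = filter_targets([fake(49), fake(50), fake(51)], min_train_pairs=50)
    assert [s.target_id for s in kept] == ["t50", "t51"]
    assert filter_targets([], 50) == []


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------


def test_chemical_diversity_shared_scaffold():
    records = [
        _record(f"c{k}", _analog(f).smiles, 6.0)
        for k, f in enumerate(["C", "N", "O", "F", "Cl", "Br", "SC", "I", "CC", "OC"])
    ]
    assert chemical_diversity(records) == pytest.approx(0.1)


def test_chemical_diversity_distinct_and_acyclic():
    distinct = [
        _record("a", "c1ccccc1O", 5),
        _record("b", "C1CCNCC1", 5),
        _record("c", "c1ccc2ccccc2c1", 5),
    ]
    assert chemical_diversity(distinct) == 1.0
    acyclic = [_record("a", "CCO", 5), _record("b", "CCCC", 5)]
    # both share the sentinel "none" scaffold
    assert chemical_diversity(acyclic) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        chemical_diversity([])


def test_chemical_diversity_bruteforce_toy():
    smiles = ["CCc1ccccc1", "CCCc1ccccc1", "c1ccncc1", "CCCC", "CCC"]
    records = [_record(f"c{k}", s, 5.0) for k, s in enumerate(smiles)]
    # brute force: benzene, pyridine, none -> 3 distinct / 5
    assert chemical_diversity(records) == pytest.approx(3 / 5)
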
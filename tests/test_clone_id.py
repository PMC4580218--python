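import itertools
import math

import numpy as np
import pytest

import clonetrack as ct
from clonetrack.clone_id import DistanceMatrix
from clonetrack.io_geno import SampleMeta

from conftest import random_genotypes


def make_G(rows, missing=None):
    rows = np.asarray(rows)
    return ct.GenotypeMatrix(
        [f"s{i}" for i in range(rows.shape[0])],
        [f"l{j}" for j in range(rows.shape[1])],
        rows,
        missing,
    )


# ---------------------------------------------------------------------------
# IBS distance


@pytest.mark.parametrize(
    "ga,gb,expected",
    [
        ([0, 1, 2, 1], [0, 1, 2, 1], 0.0),
        ([0, 2], [2, 0], 1.0),
        ([0, 1, 2, 1], [0, 2, 2, 0], 0.25),  # (0 + 0.5 + 0 + 0.5) / 4
    ],
)
def test_ibs_hand_examples(ga, gb, expected):
    D = ct.ibs_distance(make_G([ga, gb]))
    assert D.d[0, 1] == pytest.approx(expected)
    assert D.d[1, 0] == pytest.approx(expected)
    assert D.d[0, 0] == 0.0


def test_ibs_pairwise_complete_and_zero_overlap_error():
    missing = np.array([[False, True], [True, False]])
    with pytest.raises(ValueError, match="share no observed loci"):
        ct.ibs_distance(make_G([[0, 0], [2, 2]], missing))
    # one shared locus only
    missing = np.array([[False, True], [False, False]])
    D = ct.ibs_distance(make_G([[0, 0], [2, 2]], missing))
    assert D.d[0, 1] == pytest.approx(1.0)
    assert D.n_shared[0, 1] == 1


def test_ibs_symmetric_bounded_semimetric(rng):
    G = random_genotypes(rng, 12, 60, missing_rate=0.2)
    D = ct.ibs_distance(G)
    assert np.allclose(D.d, D.d.T)
    assert (D.d >= 0).all() and (D.d <= 1).all()
    assert np.allclose(np.diag(D.d), 0)


# ---------------------------------------------------------------------------
# Ward tree vs brute-force Lance-Williams oracle


def brute_ward_cophenetic(d):
    """O(n^3) Ward agglomeration via the Lance-Williams squared-distance
    update, lowest-pair-index tie-break; returns the cophenetic matrix."""
    n = d.shape[0]
    clusters = {i: (1, [i]) for i in range(n)}
    d2 = {(i, j): d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)}

    def key(a, b):
        return (a, b) if a < b else (b, a)

    coph = np.zeros((n, n))
    nxt = n
    while len(clusters) > 1:
        keys = sorted(clusters)
        dd, a, b = min(
            (d2[key(a, b)], a, b)
            for ai, a in enumerate(keys)
            for b in keys[ai + 1 :]
        )
        h = math.sqrt(dd)
        na, la = clusters[a]
        nb, lb = clusters[b]
        for x in la:
            for y in lb:
                coph[x, y] = coph[y, x] = h
        for k in keys:
            if k in (a, b):
                continue
            nk = clusters[k][0]
            d2[key(nxt, k)] = (
                (na + nk) * d2[key(a, k)] + (nb + nk) * d2[key(b, k)] - nk * dd
            ) / (na + nb + nk)
        clusters[nxt] = (na + nb, la + lb)
        del clusters[a], clusters[b]
        nxt += 1
    return coph


@pytest.mark.parametrize("seed", range(6))
def test_ward_agrees_with_bruteforce_oracle(seed):
    rng = np.random.default_rng(seed)
    G = random_genotypes(rng, 8, 40, missing_rate=0.0)
    D = ct.ibs_distance(G)
    tree = ct.ward_tree(D)
    assert np.allclose(tree.cophenetic(), brute_ward_cophenetic(D.d), atol=1e-10)


def test_ward_two_samples_and_height_monotonicity(rng):
    D2 = ct.ibs_distance(make_G([[0, 1, 2], [2, 1, 0]]))
    tree2 = ct.ward_tree(D2)
    assert tree2.merges.shape == (1, 4)
    assert tree2.merges[0, 2] == pytest.approx(D2.d[0, 1])
    G = random_genotypes(rng, 15, 50)
    tree = ct.ward_tree(ct.ibs_distance(G))
    assert (np.diff(tree.heights) >= -1e-12).all()


def test_ward_tight_pairs_merge_first():
    # 2 tight pairs: within-pair distance tiny, between ~0.5
    d = np.array(
        [
            [0.0, 0.01, 0.5, 0.52],
            [0.01, 0.0, 0.51, 0.5],
            [0.5, 0.51, 0.0, 0.01],
            [0.52, 0.5, 0.01, 0.0],
        ]
    )
    D = DistanceMatrix(["a", "b", "c", "d"], d, np.full((4, 4), 10))
    tree = ct.ward_tree(D)
    first_two = {frozenset(map(int, tree.merges[i, :2])) for i in range(2)}
    assert first_two == {frozenset({0, 1}), frozenset({2, 3})}
    nwk = tree.to_newick()
    assert nwk.endswith(";") and all(s in nwk for s in "abcd")


# ---------------------------------------------------------------------------
# threshold calibration


def lib_meta(groups):
    return [
        SampleMeta(s, "library", duplicate_group=g)
        for g, members in groups.items()
        for s in members
    ]


def test_calibrate_matches_adopted_threshold():
    """Duplicate distances {0.03, 0.04} with safety factor 1.25 -> 0.05."""
    d = np.array(
        [
            [0.0, 0.03, 0.4, 0.4],
            [0.03, 0.0, 0.4, 0.4],
            [0.4, 0.4, 0.0, 0.04],
            [0.4, 0.4, 0.04, 0.0],
        ]
    )
    D = DistanceMatrix(["a1", "a2", "b1", "b2"], d, np.full((4, 4), 100))
    meta = lib_meta({"A": ["a1", "a2"], "B": ["b1", "b2"]})
    t = ct.calibrate_threshold(D, meta)
    assert t.value == pytest.approx(0.05)
    assert t.duplicate_distances == [0.03, 0.04]


def test_calibrate_degenerate_zero_distance_warns():
    d = np.array([[0.0, 0.0], [0.0, 0.0]])
    D = DistanceMatrix(["a1", "a2"], d, np.full((2, 2), 100))
    with pytest.warns(UserWarning, match="degenerate"):
        t = ct.calibrate_threshold(D, lib_meta({"A": ["a1", "a2"]}))
    assert t.value == 0.0


def test_calibrate_requires_duplicates():
    d = np.array([[0.0, 0.2], [0.2, 0.0]])
    D = DistanceMatrix(["a", "b"], d, np.full((2, 2), 100))
    with pytest.raises(ValueError, match="manually"):
        ct.calibrate_threshold(D, [SampleMeta("a", "field"), SampleMeta("b", "field")])


def test_calibrated_threshold_separates_simulated_library():
    """At a 3 % het-miscall rate the calibrated threshold splits duplicate
    pairs from distinct-clone pairs exhaustively."""
    rng = np.random.default_rng(77)
    F = ct.simulate_founders(4, 1200, rng=rng)
    Q, _ = ct.design_q(4, 5, rng=rng)
    genets = ct.simulate_genotypes(F, Q, rng=rng)
    lib, meta = ct.make_clonal_copies(genets, genets.sample_ids, 2, 0.03, 0.0, seed=78)
    lib = lib.subset(samples=[m.sample_id for m in meta])
    D = ct.ibs_distance(lib)
    t = ct.calibrate_threshold(D, meta)
    grp = {m.sample_id: m.duplicate_group for m in meta}
    for i, j in itertools.combinations(range(len(lib.sample_ids)), 2):
        same = grp[lib.sample_ids[i]] == grp[lib.sample_ids[j]]
        if same:
            assert D.d[i, j] < t.value
        else:
            assert D.d[i, j] > t.value


# ---------------------------------------------------------------------------
# clone groups


def test_all_distant_gives_singletons(rng):
    G = random_genotypes(rng, 6, 80, missing_rate=0.0)
    D = ct.ibs_distance(G)
    t = min(D.d[i, j] for i in range(6) for j in range(i + 1, 6)) / 2
    assign = ct.clone_groups(D, t)
    assert len(assign.groups) == 6


def test_chain_rule_divergence():
    """A-B = 0.04, B-C = 0.04, A-C = 0.08, t = 0.05: the components rule
    chains all three into one group."""
    d = np.array([[0.0, 0.04, 0.08], [0.04, 0.0, 0.04], [0.08, 0.04, 0.0]])
    D = DistanceMatrix(["A", "B", "C"], d, np.full((3, 3), 100))
    comp = ct.clone_groups(D, 0.05, rule="components")
    assert len(comp.groups) == 1
    assert sorted(next(iter(comp.groups.values())).members) == ["A", "B", "C"]
    # the tree-cut rule may or may not keep them together; it must still partition
    cut = ct.clone_groups(D, 0.05, rule="tree_cut")
    assert sorted(s for g in cut.groups.values() for s in g.members) == ["A", "B", "C"]


def test_components_monotone_coarsening(rng):
    G = random_genotypes(rng, 14, 60, missing_rate=0.1)
    D = ct.ibs_distance(G)
    a1 = ct.clone_groups(D, 0.2, rule="components")
    a2 = ct.clone_groups(D, 0.35, rule="components")
    # every group at the smaller threshold is contained in one group at the larger
    for g in a1.groups.values():
        targets = {a2.assignments[s] for s in g.members}
        assert len(targets) == 1


def test_duplicate_pairs_recovered_under_both_rules():
    rng = np.random.default_rng(9)
    F = ct.simulate_founders(4, 1500, rng=rng)
    Q, _ = ct.design_q(4, 8, rng=rng)  # 32 genets
    genets = ct.simulate_genotypes(F, Q, rng=rng)
    lib, meta = ct.make_clonal_copies(genets, genets.sample_ids, 2, 0.02, 0.0, seed=10)
    lib = lib.subset(samples=[m.sample_id for m in meta])  # 64 samples, 32 pairs
    D = ct.ibs_distance(lib)
    t = ct.calibrate_threshold(D, meta)
    for rule in ("components", "tree_cut"):
        assign = ct.clone_groups(D, t, rule=rule)
        sizes = sorted(len(g.members) for g in assign.groups.values())
        assert sizes == [2] * 32


# ---------------------------------------------------------------------------
# library collapse and matching


def test_collapse_identity_without_duplicates(rng):
    G = random_genotypes(rng, 8, 100, missing_rate=0.0)
    lib = ct.collapse_library(G, 0.01)
    assert len(lib) == 8


def test_collapse_merges_synonymous_landraces():
    rng = np.random.default_rng(55)
    F = ct.simulate_founders(2, 1000, rng=rng)
    Q, _ = ct.design_q(2, 1, rng=rng)
    genets = ct.simulate_genotypes(F, Q, rng=rng)
    lib_G, _ = ct.make_clonal_copies(genets, ["S0000"], 2, 0.001, 0.0, seed=56)
    lib_G = lib_G.subset(samples=["S0000_rep1", "S0000_rep2", "S0001"])
    meta = [
        SampleMeta("S0000_rep1", "library", elicited_name="Debor"),
        SampleMeta("S0000_rep2", "library", elicited_name="Ankra"),
        SampleMeta("S0001", "library", elicited_name="Nkabom"),
    ]
    lib = ct.collapse_library(lib_G, 0.05, meta)
    assert len(lib) == 2
    merged = next(c for c in lib.cultivars if len(c.members) == 2)
    assert set(merged.synonyms) == {"Debor", "Ankra"}


def test_match_exact_copy_and_unrepresented(rng):
    G = random_genotypes(rng, 6, 200, missing_rate=0.0)
    lib = ct.collapse_library(G.subset(samples=G.sample_ids[:4]), 0.01)
    # field: an identical copy of the first library sample plus an unrelated one
    first = G.sample_ids[0]
    field = G.subset(samples=[first, G.sample_ids[5]])
    field = ct.GenotypeMatrix(["f_clone", "f_new"], field.locus_ids,
                              field.dosage, field.missing)
    assign = ct.match_to_library(field, lib, 0.05)
    g_clone = assign.groups[assign.assignments["f_clone"]]
    g_new = assign.groups[assign.assignments["f_new"]]
    assert g_clone.matched_library_cultivar == first
    assert g_clone.matched_distance == pytest.approx(0.0)
    assert g_new.matched_library_cultivar is None


def test_match_disjoint_loci_error(rng):
    A = random_genotypes(rng, 3, 10, prefix="a")
    B = random_genotypes(rng, 3, 10, prefix="b")
    with pytest.raises(ValueError, match="disjoint"):
        ct.cross_ibs_distance(A, B)
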
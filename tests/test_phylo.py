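"""Distance matrices, neighbor joining, bootstrap and rooting."""

import itertools
from collections import Counter

import dendropy
import numpy as np
import pytest

from ddscan.phylo import (
    DistanceMatrix,
    OutgroupError,
    bipartitions,
    bootstrap_supports,
    check_monophyly,
    nj_tree,
    pdistance_matrix,
    root_with_outgroup,
)
from ddscan.simulate import evolve_on_tree

# ---------------------------------------------------------------------------
# p-distances


def test_pdistance_basic_cases():
    seqs = [("a", "AAAAAAAAAA"), ("b", "AAAAAAAAAA"), ("c", "CCCCCCCCCC"),
            ("d", "AAAAACCCCC")]
    D = pdistance_matrix(seqs)
    i = {t: k for k, t in enumerate(D.taxa)}
    assert D.d[i["a"], i["b"]] == 0.0
    assert D.d[i["a"], i["c"]] == 1.0
    assert D.d[i["a"], i["d"]] == 0.5


def test_pdistance_excludes_gapped_columns():
    seqs = [("a", "AA--AA"), ("b", "AACCAA"), ("c", "CCCCCC")]
    D = pdistance_matrix(seqs)
    assert D.d[0, 1] == 0.0  # only 4 comparable columns, all equal


def test_pdistance_errors():
    with pytest.raises(ValueError):
        pdistance_matrix([("a", "AA"), ("b", "AA")])  # < 3 sequences
    with pytest.raises(ValueError):
        pdistance_matrix([("a", "AA"), ("b", "AAA"), ("c", "AA")])
    with pytest.raises(ValueError, match="comparable"):
        pdistance_matrix([("a", "A-"), ("b", "-A"), ("c", "AA")])


# ---------------------------------------------------------------------------
# NJ: closed-form and brute-force oracles


def test_three_taxon_closed_form():
    D = DistanceMatrix(taxa=("A", "B", "C"),
                       d=np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float))
    tree = nj_tree(D)
    lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
    assert lengths == pytest.approx({"A": 1.0, "B": 1.0, "C": 3.0})


def _tree_distances(topology, lengths):
    """Path distances on a 4-taxon unrooted tree ((p,q),(r,s)) with pendant
    lengths and one internal edge."""
    (p, q), (r, s) = topology
    lp, lq, lr, ls, e = lengths
    d = {
        frozenset((p, q)): lp + lq,
        frozenset((r, s)): lr + ls,
        frozenset((p, r)): lp + e + lr,
        frozenset((p, s)): lp + e + ls,
        frozenset((q, r)): lq + e + lr,
        frozenset((q, s)): lq + e + ls,
    }
    return d


def _ls_fit(topology, dist):
    """Least-squares branch lengths for a fixed 4-taxon topology."""
    (p, q), (r, s) = topology
    taxa = [p, q, r, s]
    pairs = list(itertools.combinations(taxa, 2))
    # columns: lp, lq, lr, ls, e
    def row(a, b):
        v = [0.0] * 5
        for t, k in zip(taxa, range(4)):
            if t in (a, b):
                v[k] = 1.0
        same_side = {a, b} in ({p, q}, {r, s})
        v[4] = 0.0 if same_side else 1.0
        return v

    A = np.array([row(a, b) for a, b in pairs])
    y = np.array([dist[frozenset((a, b))] for a, b in pairs])
    x, res, *_ = np.linalg.lstsq(A, y, rcond=None)
    fitted = A @ x
    return x, float(((fitted - y) ** 2).sum())


def test_four_taxon_additive_recovery_against_ls_oracle():
    """NJ must recover exactly the topology and lengths that the brute-force
    least-squares fit over all three unrooted topologies identifies."""
    true_topo = (("A", "B"), ("C", "D"))
    true_lengths = (1.0, 2.0, 3.0, 1.0, 1.5)
    dist = _tree_distances(true_topo, true_lengths)

    topologies = [
        (("A", "B"), ("C", "D")),
        (("A", "C"), ("B", "D")),
        (("A", "D"), ("B", "C")),
    ]
    fits = [(t, *_ls_fit(t, dist)) for t in topologies]
    best_topo, best_x, best_rss = min(fits, key=lambda f: f[2])
    assert best_topo == true_topo and best_rss == pytest.approx(0.0, abs=1e-12)

    taxa = ("A", "B", "C", "D")
    d = np.zeros((4, 4))
    for i, a in enumerate(taxa):
        for j, b in enumerate(taxa):
            if i != j:
                d[i, j] = dist[frozenset((a, b))]
    tree = nj_tree(DistanceMatrix(taxa=taxa, d=d))
    assert bipartitions(tree) == {
        frozenset({frozenset({"A", "B"}), frozenset({"C", "D"})})
    }
    leaf_len = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
    assert leaf_len == pytest.approx(dict(zip("ABCD", best_x[:4])))
    internal = [
        nd.edge.length
        for nd in tree.preorder_node_iter()
        if nd is not tree.seed_node and not nd.is_leaf()
    ]
    assert internal == pytest.approx([best_x[4]])


def test_nj_consistent_on_random_additive_matrices():
    """Noise-free additive distances from random trees are recovered exactly."""
    rng = np.random.default_rng(99)
    for _ in range(5):
        n = 6
        taxa = [f"t{i}" for i in range(n)]
        tree = dendropy.simulate.treesim.birth_death_tree(
            birth_rate=1.0, death_rate=0.0, num_extant_tips=n,
            rng=__import__("random").Random(int(rng.integers(1 << 30))),
        )
        for i, leaf in enumerate(tree.leaf_node_iter()):
            leaf.taxon.label = taxa[i]
        for e in tree.preorder_edge_iter():
            if e.length is not None:
                e.length = float(rng.uniform(0.5, 2.0))
        pdm = tree.phylogenetic_distance_matrix()
        d = np.zeros((n, n))
        tx = {t.label: t for t in tree.taxon_namespace}
        for i, a in enumerate(taxa):
            for j, b in enumerate(taxa):
                if i != j:
                    d[i, j] = pdm.distance(tx[a], tx[b])
        rebuilt = nj_tree(DistanceMatrix(taxa=tuple(taxa), d=d))
        assert bipartitions(rebuilt) == bipartitions(tree)


def test_nj_preserves_leaf_set():
    rng = np.random.default_rng(1)
    n = 7
    m = rng.uniform(0.1, 1.0, (n, n))
    d = (m + m.T) / 2
    np.fill_diagonal(d, 0.0)
    taxa = tuple(f"x{i}" for i in range(n))
    tree = nj_tree(DistanceMatrix(taxa=taxa, d=d))
    assert {l.taxon.label for l in tree.leaf_node_iter()} == set(taxa)


def test_nj_rejects_nonfinite():
    d = np.zeros((3, 3))
    d[0, 1] = d[1, 0] = np.inf
    with pytest.raises(ValueError):
        DistanceMatrix(taxa=("a", "b", "c"), d=d)


def test_newick_roundtrip():
    D = DistanceMatrix(taxa=("A", "B", "C", "D"),
                       d=np.array([[0, 1, 2, 2], [1, 0, 2, 2],
                                   [2, 2, 0, 1], [2, 2, 1, 0]], float))
    tree = nj_tree(D)
    nwk = tree.as_string(schema="newick")
    back = dendropy.Tree.get(data=nwk, schema="newick")
    assert bipartitions(back) == bipartitions(tree)


# ---------------------------------------------------------------------------
# bootstrap


PERFECT_SPLIT = [("A", "A" * 20), ("B", "A" * 20), ("C", "C" * 20), ("D", "C" * 20)]


def test_bootstrap_rejects_zero_reps():
    with pytest.raises(ValueError):
        bootstrap_supports(PERFECT_SPLIT, n_reps=0, seed=1)


def test_perfectly_supported_split_has_support_one():
    _, sup = bootstrap_supports(PERFECT_SPLIT, n_reps=25, seed=1)
    assert list(sup.values()) == [1.0]


def test_bootstrap_supports_are_seed_deterministic():
    seqs = [("A", "ACGTACGTAAGGTACAGTCA"), ("B", "ACGTACGTAAGGTACAGACA"),
            ("C", "TCGAACGAAAGCTACAGTCT"), ("D", "TCGAACCAAAGCTTCAGTCT"),
            ("E", "TCGTACCAAAGCTTCTGTCT")]
    _, s1 = bootstrap_supports(seqs, n_reps=30, seed=42)
    _, s2 = bootstrap_supports(seqs, n_reps=30, seed=42)
    assert s1 == s2
    _, s3 = bootstrap_supports(seqs, n_reps=30, seed=43)
    assert s3.keys() == s1.keys()  # same tree, possibly different supports


def test_supports_annotated_on_internal_nodes():
    tree, sup = bootstrap_supports(PERFECT_SPLIT, n_reps=10, seed=0)
    labels = [nd.label for nd in tree.preorder_node_iter()
              if nd is not tree.seed_node and not nd.is_leaf()]
    assert labels == ["1.000"]


EIGHT_TAXON_NEWICK = (
    "(((A:1,B:1):1,(C:1,D:1):1):1,((E:1,F:1):1,(G:1,H:1):1):1);"
)


def test_modal_bootstrap_tree_recovers_generating_topology():
    """Sequences evolved at ~0.05 substitutions/site/edge on a known
    8-taxon tree: the modal bootstrap topology matches the generator in
    >= 90% of seeded runs."""
    gen_tree = dendropy.Tree.get(data=EIGHT_TAXON_NEWICK, schema="newick")
    true_bips = bipartitions(gen_tree)
    root_seq = "ACDEFGHIKLMNPQRSTVWY" * 15  # 300 sites
    hits = 0
    runs, reps = 50, 12
    for run in range(runs):
        tips = evolve_on_tree(EIGHT_TAXON_NEWICK, root_seq, rate=0.05, seed=1000 + run)
        seqs = sorted(tips.items())
        L = len(root_seq)
        rng_streams = np.random.SeedSequence(500 + run).spawn(reps)
        topo_counts = Counter()
        for r in range(reps):
            rng = np.random.default_rng(rng_streams[r])
            cols = rng.integers(0, L, size=L)
            res = [(t, "".join(s[c] for c in cols)) for t, s in seqs]
            topo = frozenset(bipartitions(nj_tree(pdistance_matrix(res))))
            topo_counts[topo] += 1
        modal = topo_counts.most_common(1)[0][0]
        if set(modal) == true_bips:
            hits += 1
    assert hits / runs >= 0.90


# ---------------------------------------------------------------------------
# rooting and monophyly


def _ab_cd_tree():
    D = DistanceMatrix(taxa=("A", "B", "C", "D"),
                       d=np.array([[0, 1, 3, 3], [1, 0, 3, 3],
                                   [3, 3, 0, 1], [3, 3, 1, 0]], float))
    return nj_tree(D)


def test_root_with_single_leaf_outgroup_preserves_bipartitions():
    tree = _ab_cd_tree()
    rooted = root_with_outgroup(tree, {"A"})
    assert rooted.is_rooted
    assert bipartitions(rooted) == bipartitions(tree)


def test_root_with_clade_outgroup():
    tree = _ab_cd_tree()
    rooted = root_with_outgroup(tree, {"C", "D"})
    assert bipartitions(rooted) == bipartitions(tree)


def test_outgroup_all_taxa_rejected():
    tree = _ab_cd_tree()
    with pytest.raises(OutgroupError):
        root_with_outgroup(tree, {"A", "B", "C", "D"})


def test_non_monophyletic_outgroup_rejected():
    tree = _ab_cd_tree()
    with pytest.raises(OutgroupError):
        root_with_outgroup(tree, {"A", "C"})


def test_rooting_roundtrip_on_random_trees():
    rng = np.random.default_rng(5)
    for _ in range(5):
        n = 8
        taxa = tuple(f"t{i}" for i in range(n))
        m = rng.uniform(0.2, 1.0, (n, n))
        d = (m + m.T) / 2
        np.fill_diagonal(d, 0.0)
        tree = nj_tree(DistanceMatrix(taxa=taxa, d=d))
        leaf = taxa[int(rng.integers(0, n))]
        rooted = root_with_outgroup(tree, {leaf})
        assert bipartitions(rooted) == bipartitions(tree)


def test_monophyly_calls():
    tree = _ab_cd_tree()
    assert check_monophyly(tree, {"A": "x", "B": "x", "C": "y", "D": "y"}) == {
        "x": True, "y": True}
    assert check_monophyly(tree, {"A": "x", "B": "y", "C": "x", "D": "y"}) == {
        "x": False, "y": False}
    # singleton convention
    assert check_monophyly(tree, {"A": "s", "B": "y", "C": "y", "D": "y"})["s"] is True
    with pytest.raises(ValueError, match="unlabeled"):
        check_monophyly(tree, {"A": "x"})
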
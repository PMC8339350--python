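"""Distance-based phylogeny with bootstrap supports and outgroup rooting.

The tree stage is neighbor joining on p-distances with classical
(Felsenstein) column-resampling bootstrap proportions.  Trees are carried as
:class:`dendropy.Tree` objects throughout, so newick serialization, rooting
and bipartition bookkeeping follow that library's conventions; supports are
written as internal-node labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Set, Tuple

import dendropy
import numpy as np

AlignedSeqs = Sequence[Tuple[str, str]]  # (taxon id, gapped sequence)

Bipartition = FrozenSet[FrozenSet[str]]


@dataclass(frozen=True)
class DistanceMatrix:
    taxa: Tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if d.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if not np.all(np.isfinite(d)):
            raise ValueError("distances must be finite")
        if np.any(d < 0) or not np.allclose(d, d.T) or np.any(np.diag(d) != 0):
            raise ValueError("matrix must be symmetric, non-negative, zero-diagonal")
        object.__setattr__(self, "d", d)

    def to_phylip(self) -> str:
        lines = [f" {len(self.taxa)}"]
        for t, row in zip(self.taxa, self.d):
            lines.append(t + "  " + "  ".join(f"{x:.6f}" for x in row))
        return "\n".join(lines) + "\n"


def pdistance_matrix(seqs: AlignedSeqs) -> DistanceMatrix:
    """Pairwise p-distances over an alignment.

    d[i][j] = mismatches / comparable columns, where a column is comparable
    for the pair when neither sequence has a gap there.
    """
    seqs = list(seqs)
    if len(seqs) < 3:
        raise ValueError("need at least 3 sequences")
    L = len(seqs[0][1])
    if any(len(s) != L for _, s in seqs):
        raise ValueError("aligned sequences must have equal length")
    arr = np.array([list(s) for _, s in seqs])
    gap = (arr == "-") | (arr == ".")
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(gap[i] | gap[j])
            comparable = int(ok.sum())
            if comparable == 0:
                raise ValueError(
                    f"no comparable columns between {seqs[i][0]} and {seqs[j][0]}"
                )
            mism = int((arr[i][ok] != arr[j][ok]).sum())
            d[i, j] = d[j, i] = mism / comparable
    return DistanceMatrix(taxa=tuple(t for t, _ in seqs), d=d)


def nj_tree(D: DistanceMatrix) -> dendropy.Tree:
    """Neighbor joining (Saitou-Nei, Studier-Keppler Q-criterion).

    Deterministic: ties in Q break toward the lowest (i, j) taxon-index
    pair.  Negative branch lengths are clamped to zero with the deficit
    moved onto the sibling edge.  The returned tree is unrooted
    (trifurcating seed node).
    """
    n = len(D.taxa)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    tns = dendropy.TaxonNamespace(list(D.taxa))
    nodes: List[dendropy.Node] = [
        dendropy.Node(taxon=tns.get_taxon(t)) for t in D.taxa
    ]
    d = D.d.copy()
    active = list(range(n))

    def _clamp(li: float, lj: float) -> Tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest-index tie-break: argmin scans row-major over (i, j)
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                if best is None or q[a, b] < best[0] - 1e-12:
                    best = (q[a, b], a, b)
        _, a, b = best
        i, j = active[a], active[b]
        li = sub[a, b] / 2 + (r[a] - r[b]) / (2 * (m - 2))
        lj = sub[a, b] - li
        li, lj = _clamp(li, lj)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        # distances from the new node to every other active node
        dk = (d[i, :] + d[j, :] - d[i, j]) / 2
        d = np.vstack([d, dk])
        dk2 = np.append(dk, 0.0)
        d = np.column_stack([d, dk2])
        nodes.append(parent)
        new_idx = d.shape[0] - 1
        active = [x for x in active if x not in (i, j)] + [new_idx]

    # terminal three-point join
    i, j, k = active
    dij, dik, djk = d[i, j], d[i, k], d[j, k]
    li = (dij + dik - djk) / 2
    lj = (dij + djk - dik) / 2
    lk = (dik + djk - dij) / 2
    root = dendropy.Node()
    for idx, ln in ((i, li), (j, lj), (k, lk)):
        root.add_child(nodes[idx])
        nodes[idx].edge.length = max(ln, 0.0)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# bipartitions


def _leaf_labels(tree: dendropy.Tree) -> FrozenSet[str]:
    return frozenset(l.taxon.label for l in tree.leaf_node_iter())


def edge_sides(tree: dendropy.Tree) -> Dict[int, FrozenSet[str]]:
    """For every non-seed node, the leaf-label set below its subtending edge."""
    sides: Dict[int, FrozenSet[str]] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            sides[id(nd)] = frozenset([nd.taxon.label])
        else:
            acc: Set[str] = set()
            for c in nd.child_nodes():
                acc |= sides[id(c)]
            sides[id(nd)] = frozenset(acc)
    return sides


def bipartitions(tree: dendropy.Tree) -> Set[Bipartition]:
    """Non-trivial bipartitions (both sides >= 2), rooting-invariant."""
    leaves = _leaf_labels(tree)
    sides = edge_sides(tree)
    bips: Set[Bipartition] = set()
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node:
            continue
        below = sides[id(nd)]
        other = leaves - below
        if len(below) >= 2 and len(other) >= 2:
            bips.add(frozenset({below, other}))
    return bips


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_supports(
    seqs: AlignedSeqs, n_reps: int, seed: int
) -> Tuple[dendropy.Tree, Dict[Bipartition, float]]:
    """NJ tree from the full alignment plus bootstrap proportions.

    Columns are resampled with replacement ``n_reps`` times; each replicate
    uses an independent substream spawned from ``seed``, so results are
    reproducible and independent of evaluation order.  Supports are written
    onto the internal-node labels of the returned tree.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    seqs = list(seqs)
    L = len(seqs[0][1])
    tree = nj_tree(pdistance_matrix(seqs))
    counts: Dict[Bipartition, int] = {b: 0 for b in bipartitions(tree)}

    streams = np.random.SeedSequence(seed).spawn(n_reps)
    for rep in range(n_reps):
        rng = np.random.default_rng(streams[rep])
        cols = rng.integers(0, L, size=L)
        resampled = [
            (t, "".join(s[c] for c in cols)) for t, s in seqs
        ]
        rep_bips = bipartitions(nj_tree(pdistance_matrix(resampled)))
        for b in counts:
            if b in rep_bips:
                counts[b] += 1

    supports = {b: c / n_reps for b, c in counts.items()}
    annotate_supports(tree, supports)
    return tree, supports


def annotate_supports(
    tree: dendropy.Tree, supports: Mapping[Bipartition, float]
) -> None:
    leaves = _leaf_labels(tree)
    sides = edge_sides(tree)
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node or nd.is_leaf():
            continue
        below = sides[id(nd)]
        bip = frozenset({below, leaves - below})
        if bip in supports:
            nd.label = f"{supports[bip]:.3f}"


# ---------------------------------------------------------------------------
# rooting and clade checks


class OutgroupError(ValueError):
    """Outgroup taxa are missing or not monophyletic in the unrooted tree."""


def root_with_outgroup(
    tree: dendropy.Tree, outgroup_taxa: Set[str]
) -> dendropy.Tree:
    """Root on the edge separating the outgroup from the ingroup.

    The input tree is left untouched; the rooted tree is a clone.  The
    unrooted bipartition set is preserved.
    """
    leaves = _leaf_labels(tree)
    og = frozenset(outgroup_taxa)
    if not og or not og <= leaves:
        raise OutgroupError("outgroup taxa must be a non-empty subset of the leaves")
    if og == leaves:
        raise OutgroupError("outgroup cannot contain every taxon")

    rooted = tree.clone(depth=1)
    sides = edge_sides(rooted)
    target = None
    for nd in rooted.preorder_node_iter():
        if nd is rooted.seed_node:
            continue
        below = sides[id(nd)]
        if below == og or leaves - below == og:
            target = nd
            break
    if target is None:
        raise OutgroupError("outgroup is not monophyletic in the unrooted tree")
    L = target.edge.length or 0.0
    rooted.reroot_at_edge(
        target.edge, length1=L / 2, length2=L / 2, update_bipartitions=False
    )
    rooted.is_rooted = True
    return rooted


def check_monophyly(
    tree: dendropy.Tree, labels: Mapping[str, str]
) -> Dict[str, bool]:
    """For each class, is there an edge isolating exactly that class's leaves?

    Single-member classes are monophyletic by convention.
    """
    leaves = _leaf_labels(tree)
    missing = leaves - set(labels)
    if missing:
        raise ValueError(f"unlabeled leaves: {sorted(missing)}")
    classes: Dict[str, Set[str]] = {}
    for taxon, cls in labels.items():
        if taxon in leaves:
            classes.setdefault(cls, set()).add(taxon)
    all_sides = set()
    sides = edge_sides(tree)
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node:
            continue
        below = sides[id(nd)]
        all_sides.add(below)
        all_sides.add(leaves - below)
    return {
        cls: (len(members) == 1 or frozenset(members) in all_sides)
        for cls, members in classes.items()
    }


def write_newick(tree: dendropy.Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            tree.as_string(
                schema="newick", suppress_rooting=True, real_value_format_specifier=".6f"
            )
        )
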
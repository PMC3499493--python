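"""Neighbor-joining trees, bootstrap supports, and species cohesion.

The agglomeration is Saitou & Nei's Q-criterion in the Studier-Keppler
form.  Ties in Q are broken by the lowest pair index in node-creation
order, so a given matrix always yields the same tree; negative branch
estimates are clamped to zero.  On additive distances the generating
topology and branch lengths are recovered exactly.

Bootstrap supports are percentages of column-resampled replicates whose
NJ tree contains the same leaf bipartition, mapped onto the original
tree's internal edges.  A species "clusters cohesively" when its leaves
form an exclusive clade under some rooting, i.e. one edge separates
exactly those leaves from the rest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Set

import numpy as np

from .distances import DistanceMatrix, _matrix_from_classes, encode_alignment, pair_classes
from .seqio import AlignedSet, BarcodeRecord

__all__ = ["TreeNode", "BarcodeTree", "nj", "bootstrap_supports", "is_cohesive"]


@dataclass
class TreeNode:
    """Tree node: leaves carry a label, internal nodes optionally a support."""

    label: Optional[str] = None
    length: float = 0.0
    children: List["TreeNode"] = field(default_factory=list)
    support: Optional[float] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_labels(self) -> List[str]:
        if self.is_leaf:
            return [self.label]
        out: List[str] = []
        for c in self.children:
            out.extend(c.leaf_labels())
        return out


@dataclass
class BarcodeTree:
    """Unrooted NJ tree, stored rooted at the final (trifurcating) join."""

    root: TreeNode

    @property
    def leaves(self) -> List[str]:
        return self.root.leaf_labels()

    def clades(self) -> Dict[FrozenSet[str], TreeNode]:
        """Leaf set below every non-root node (each edge's child side)."""
        out: Dict[FrozenSet[str], TreeNode] = {}

        def walk(node: TreeNode) -> FrozenSet[str]:
            if node.is_leaf:
                s = frozenset([node.label])
            else:
                s = frozenset().union(*(walk(c) for c in node.children))
            if node is not self.root:
                out[s] = node
            return s

        walk(self.root)
        return out

    def bipartitions(self) -> Dict[FrozenSet[str], TreeNode]:
        """Non-trivial splits, keyed by the side not containing the first leaf.

        Each key identifies one internal edge; values are the child-side
        nodes, which is where bootstrap supports are stored.
        """
        all_leaves = frozenset(self.leaves)
        ref = min(all_leaves)
        out: Dict[FrozenSet[str], TreeNode] = {}
        for side, node in self.clades().items():
            if 1 < len(side) < len(all_leaves) - 1:
                key = side if ref not in side else all_leaves - side
                out[key] = node
        return out

    def to_newick(
        self,
        records: Optional[Mapping[str, BarcodeRecord]] = None,
        decimals: int = 6,
    ) -> str:
        """Newick with branch lengths and integer supports as internal labels.

        With ``records`` given, leaves are written ``accession|Genus_species``
        (spaces rendered as underscores).
        """

        def name(label: str) -> str:
            if records and label in records:
                return f"{label}|{records[label].species.replace(' ', '_')}"
            return label

        def fmt(node: TreeNode, top: bool = False) -> str:
            if node.is_leaf:
                body = name(node.label)
            else:
                inner = ",".join(fmt(c) for c in node.children)
                sup = (
                    ""
                    if node.support is None or top
                    else f"{node.support:.0f}"
                )
                body = f"({inner}){sup}"
            return body if top else f"{body}:{node.length:.{decimals}f}"

        return fmt(self.root, top=True) + ";"


def _nj_from_array(d: np.ndarray, labels: Sequence[str]) -> BarcodeTree:
    m = len(labels)
    nodes: List[TreeNode] = [TreeNode(label=lab) for lab in labels]
    D = d.astype(float).copy()
    while len(nodes) > 3:
        n = len(nodes)
        r = D.sum(axis=1)
        Q = (n - 2) * D - r[:, None] - r[None, :]
        iu = np.triu_indices(n, k=1)
        flat = Q[iu]
        best = int(np.argmin(flat))  # first occurrence wins ties (row-major)
        i, j = int(iu[0][best]), int(iu[1][best])
        bi = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (n - 2))
        bj = D[i, j] - bi
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length = max(0.0, bi)
        nodes[j].length = max(0.0, bj)
        dk = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        dk = np.maximum(dk, 0.0)
        # replace row i with the new node, drop row j
        D[i, :] = dk
        D[:, i] = dk
        D[i, i] = 0.0
        nodes[i] = parent
        keep = [k for k in range(n) if k != j]
        D = D[np.ix_(keep, keep)]
        nodes.pop(j)
    if len(nodes) == 3:
        b0 = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
        b1 = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
        b2 = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
        for node, b in zip(nodes, (b0, b1, b2)):
            node.length = max(0.0, b)
        root = TreeNode(children=list(nodes))
    else:  # exactly 2 remain only if the input had 3 and one join happened
        raise AssertionError("unreachable")
    return BarcodeTree(root=root)


def nj(matrix: DistanceMatrix) -> BarcodeTree:
    """Neighbor-joining tree from a distance matrix.

    Requires >=3 labels and no undefined/non-finite pairs (drop or impute
    them first, e.g. via ``DistanceMatrix.drop``).
    """
    if len(matrix.labels) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if matrix.undefined_pairs or not np.all(np.isfinite(matrix.d)):
        raise ValueError(
            "distance matrix has undefined pairs; drop those records first"
        )
    return _nj_from_array(matrix.d, matrix.labels)


def bootstrap_supports(
    aligned: AlignedSet,
    replicates: int = 1000,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    deletion: str = "pairwise",
) -> BarcodeTree:
    """NJ tree with bootstrap supports on its internal edges.

    Alignment columns are resampled with replacement per replicate and the
    NJ tree rebuilt; each internal edge's support is the percentage of
    replicates containing the same leaf bipartition.  Replicates yielding an
    undefined pair are dropped and counted; more than 10% dropped raises.
    ``replicates=0`` returns the original tree without supports.  Given the
    same seed the supports are identical.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    codes = encode_alignment(aligned)
    if deletion == "complete":
        codes = codes[:, (codes != 255).all(axis=0)]
    labels = [r.accession for r in aligned]
    classes = pair_classes(codes)
    n = len(labels)
    d, ns, undef = _matrix_from_classes(classes, n)
    if undef:
        bad = sorted({labels[i] for p in undef for i in p})
        raise ValueError(f"undefined distances involving {bad}")
    tree = _nj_from_array(d, labels)
    if replicates == 0:
        return tree
    splits = tree.bipartitions()
    counts = {key: 0 for key in splits}
    n_cols = codes.shape[1]
    dropped = 0
    for _ in range(replicates):
        cols = rng.integers(0, n_cols, size=n_cols)
        rd, _, rundef = _matrix_from_classes(classes, n, columns=cols)
        if rundef:
            dropped += 1
            continue
        rep_splits = _nj_from_array(rd, labels).bipartitions()
        for key in counts:
            if key in rep_splits:
                counts[key] += 1
    if dropped > 0.1 * replicates:
        raise RuntimeError(
            f"{dropped}/{replicates} bootstrap replicates had undefined "
            "distances; alignment too saturated for support estimation"
        )
    used = replicates - dropped
    for key, node in splits.items():
        node.support = 100.0 * counts[key] / used
    return tree


def is_cohesive(
    tree: BarcodeTree,
    species: str,
    records: Mapping[str, BarcodeRecord] | Sequence[BarcodeRecord],
    min_support: Optional[float] = None,
) -> bool:
    """True iff the species' leaves form an exclusive clade in the tree.

    Singleton species are cohesive by convention, as is a species owning
    every leaf.  With ``min_support`` set, the separating edge must also
    carry at least that bootstrap percentage.
    """
    if not isinstance(records, Mapping):
        records = {r.accession: r for r in records}
    present = set(tree.leaves)
    mine = frozenset(
        acc for acc, r in records.items() if r.species == species and acc in present
    )
    if not mine:
        raise ValueError(f"species {species!r} has no leaf in the tree")
    if len(mine) == 1 or mine == present:
        return True
    clades = tree.clades()
    complement = frozenset(present) - mine
    for side in (mine, complement):
        node = clades.get(side)
        if node is not None:
            if min_support is None or node.is_leaf:
                return True
            if node.support is not None and node.support >= min_support:
                return True
    return False
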
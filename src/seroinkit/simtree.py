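"""Pairwise similarity, class summaries and a neighbor-joining sanity tree.

Within-class seroin similarity exceeds between-class similarity, and the
three classes form deep separate branches in phylogenetic trees.  This
module provides the quantitative counterpart on any classified record set:
affine-gap global alignment identities (identity = matches / all alignment
columns, gap columns included), per-class-pair summaries, Saitou-Nei
neighbor joining on 1 - identity distances, and a class-monophyly check
with unrooted-tree semantics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

GAP_OPEN = 10.0
GAP_EXTEND = 1.0


@dataclass
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: float
    identity_pct: float


def _make_aligner(matrix: str = "BLOSUM62", gap_open: float = GAP_OPEN,
                  gap_extend: float = GAP_EXTEND) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    # first gap residue costs gap_open, each further residue gap_extend
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def global_align(a: str, b: str, matrix: str = "BLOSUM62",
                 gap_open: float = GAP_OPEN, gap_extend: float = GAP_EXTEND
                 ) -> AlignmentResult:
    """Optimal affine-gap global alignment (Gotoh) of two proteins.

    Identity is 100 x matches / alignment columns, counting gap columns
    in the denominator.  Among co-optimal alignments Biopython's first
    traceback is taken, which prefers aligned residues over gaps.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    aln = aligner.align(a, b)[0]
    sa, sb = str(aln[0]), str(aln[1])
    matches = sum(1 for x, y in zip(sa, sb) if x == y and x != "-")
    identity = 100.0 * matches / len(sa)
    return AlignmentResult(sa, sb, float(aln.score), identity)


def identity_pct(a: str, b: str) -> float:
    return global_align(a, b).identity_pct


def class_similarity_summary(records: Sequence, calls: Mapping[str, str],
                             ) -> pd.DataFrame:
    """Mean/min/max pairwise identity for every unordered class pair.

    ``records`` need ``.id`` and ``.protein``; ``calls`` maps record id to
    class.  Within-class rows with fewer than two members are marked n/a.
    """
    classes = sorted(set(calls.values()))
    pair_idents: dict[tuple[str, str], list[float]] = {}
    recs = [r for r in records if r.id in calls]
    for ra, rb in combinations(recs, 2):
        ca, cb = calls[ra.id], calls[rb.id]
        key = tuple(sorted((ca, cb)))
        pair_idents.setdefault(key, []).append(identity_pct(ra.protein, rb.protein))
    rows = []
    for ca, cb in combinations_with_self(classes):
        idents = pair_idents.get((ca, cb), [])
        if idents:
            rows.append({"class_a": ca, "class_b": cb, "n_pairs": len(idents),
                         "mean_identity": float(np.mean(idents)),
                         "min_identity": float(np.min(idents)),
                         "max_identity": float(np.max(idents))})
        else:
            rows.append({"class_a": ca, "class_b": cb, "n_pairs": 0,
                         "mean_identity": np.nan, "min_identity": np.nan,
                         "max_identity": np.nan})
    return pd.DataFrame(rows)


def combinations_with_self(items: Sequence[str]):
    for i, a in enumerate(items):
        for b in items[i:]:
            yield (a, b)


@dataclass
class DistanceMatrix:
    """Symmetric distance matrix d = 1 - identity/100 with zero diagonal."""

    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(m), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have a zero diagonal")
        self.matrix = m

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.matrix, index=self.labels, columns=self.labels
                     ).to_csv(path, sep="\t")


def distance_matrix(records: Sequence) -> DistanceMatrix:
    labels = [r.id for r in records]
    n = len(labels)
    m = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        d = 1.0 - identity_pct(records[i].protein, records[j].protein) / 100.0
        m[i, j] = m[j, i] = d
    return DistanceMatrix(labels, m)


@dataclass
class TreeNode:
    """Rooted representation of the (unrooted) NJ tree."""

    label: Optional[str] = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def to_newick(self) -> str:
        return self._newick_inner() + ";"

    def _newick_inner(self) -> str:
        if self.is_leaf:
            return self.label
        inner = ",".join(f"{c._newick_inner()}:{bl:.10g}" for c, bl in self.children)
        return f"({inner})"


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining.

    Q-criterion ties break on the smallest (i, j) label pair.  Negative
    branch lengths are clamped to zero with the deficit moved to the
    sibling branch.  The last remaining node is attached under the final
    internal node with the full residual distance, so for three taxa the
    closed-form branch lengths are returned directly.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(label=l) for l in dm.labels]
    names: list[str] = list(dm.labels)
    d = dm.matrix.astype(float).copy()
    active = list(range(n))

    while len(active) > 2:
        m = len(active)
        r = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                q = (m - 2) * d[i, j] - r[i] - r[j]
                key = tuple(sorted((names[i], names[j])))
                if best is None or q < best[0] - 1e-12 or (
                        abs(q - best[0]) <= 1e-12 and key < best[3]):
                    best = (q, i, j, key)
        _, i, j, _ = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        # clamp negatives, moving the deficit to the sibling
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        parent = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        # new distances
        new_row = np.zeros(d.shape[0] + 1)
        for k in active:
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, : -1] = new_row[:-1]
        d[: -1, -1] = new_row[:-1]
        nodes.append(parent)
        names.append(min(names[i], names[j]))
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    i, j = active
    residual = max(d[i, j], 0.0)
    # attach the earlier-created node under the later-created internal node
    root_idx, child_idx = (i, j) if i > j else (j, i)
    root = nodes[root_idx]
    if root.is_leaf:  # only possible for pathological inputs
        root, child_idx = nodes[child_idx], root_idx
        root_idx = active[0] if active[0] != child_idx else active[1]
    root.children.append((nodes[child_idx], residual))
    return root


def is_class_monophyletic(tree: TreeNode, class_labels: Mapping[str, str]
                          ) -> dict[str, bool]:
    """Per-class monophyly under unrooted bipartition semantics.

    A class is monophyletic iff some edge of the tree separates exactly
    that class's leaves from the rest (trivially true for singleton or
    all-leaf classes).
    """
    leaves = set(tree.leaves())
    unknown = leaves - set(class_labels)
    if unknown:
        raise ValueError(f"leaves without class labels: {sorted(unknown)}")
    clades: list[frozenset[str]] = []

    def collect(node: TreeNode) -> frozenset[str]:
        if node.is_leaf:
            s = frozenset([node.label])
        else:
            s = frozenset()
            for child, _ in node.children:
                s |= collect(child)
        clades.append(s)
        return s

    collect(tree)
    bipartitions = {c for c in clades} | {frozenset(leaves - c) for c in clades}
    out = {}
    for cls in sorted(set(class_labels.values())):
        members = frozenset(l for l, c in class_labels.items() if c == cls)
        out[cls] = members in bipartitions or len(members) <= 1 or members == leaves
    return out
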
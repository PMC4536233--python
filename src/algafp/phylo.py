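"""Sequence-side comparator: pairwise substitution counts, two-parameter
substitution-corrected distances with an additive gap penalty, neighbor
joining, and tree-congruence reporting."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fingerprint_clustering import Dendrogram, TreeNode
from .io_formats import SeqAlignment

_BASES = set("ACGT")
_PURINES = set("AG")
_PYRIMIDINES = set("CT")

DEFAULT_GAP_PENALTY = 0.12


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


def _is_transition(x: str, y: str) -> bool:
    return (x in _PURINES and y in _PURINES) or (
        x in _PYRIMIDINES and y in _PYRIMIDINES
    )


def pairwise_differences(a: str, b: str) -> int:
    """Count substitutions between two aligned sequences.

    Only columns where both characters are unambiguous bases count;
    gaps and N are excluded. U is treated as T.
    """
    if len(a) != len(b):
        raise ValueError("aligned sequences must have equal length")
    a, b = _normalize(a), _normalize(b)
    return sum(
        1 for x, y in zip(a, b) if x in _BASES and y in _BASES and x != y
    )


def kimura_distance(
    a: str, b: str, gap_penalty: float = DEFAULT_GAP_PENALTY
) -> float:
    """Two-parameter substitution-corrected distance between aligned
    sequences, with an additive per-gap-column penalty.

    Over the comparable sites (both characters unambiguous bases), with
    transition proportion P and transversion proportion Q:

        d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

    Each column where exactly one sequence has a gap adds
    ``gap_penalty / L_comparable`` to d. Columns where both have gaps,
    or either has N, are ignored.
    """
    if len(a) != len(b):
        raise ValueError("aligned sequences must have equal length")
    a, b = _normalize(a), _normalize(b)
    n_comp = 0
    n_ts = 0
    n_tv = 0
    n_gap = 0
    for x, y in zip(a, b):
        one_gap = (x == "-") != (y == "-")
        if one_gap:
            n_gap += 1
            continue
        if x in _BASES and y in _BASES:
            n_comp += 1
            if x != y:
                if _is_transition(x, y):
                    n_ts += 1
                else:
                    n_tv += 1
    if n_comp == 0:
        raise ValueError("no comparable sites")
    P = n_ts / n_comp
    Q = n_tv / n_comp
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise ValueError("distance saturated")
    d = -0.5 * math.log(w1 * math.sqrt(w2))
    d += gap_penalty * n_gap / n_comp
    return d


@dataclass
class DistanceMatrix:
    labels: list[str]
    D: np.ndarray

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        n = len(self.labels)
        if self.D.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.D, self.D.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.D), 0.0, atol=1e-10):
            raise ValueError("distance matrix diagonal must be 0")
        if not np.all(np.isfinite(self.D)) or self.D.min() < -1e-10:
            raise ValueError("distances must be finite and non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.D, index=self.labels, columns=self.labels)


def distance_matrix_from_alignment(
    aln: SeqAlignment, gap_penalty: float = DEFAULT_GAP_PENALTY
) -> DistanceMatrix:
    n = len(aln)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = kimura_distance(
                aln.sequences[i], aln.sequences[j], gap_penalty=gap_penalty
            )
    return DistanceMatrix(labels=list(aln.labels), D=D)


@dataclass
class PhyloTree:
    """Unrooted tree stored as a rooted representation at an arbitrary
    internal node; ``negative_branches_clamped`` flags NJ length clamping."""

    root: TreeNode
    labels: list[str]
    negative_branches_clamped: int = 0

    def to_newick(self) -> str:
        return self.root.to_newick()

    def splits(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, each encoded as the side not
        containing the first label (canonical orientation)."""
        all_leaves = frozenset(self.labels)
        anchor = min(self.labels)
        out: set[frozenset[str]] = set()

        def visit(node: TreeNode) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.label])
            fs = frozenset().union(*(visit(c) for c in node.children))
            side = fs if anchor not in fs else all_leaves - fs
            if 1 < len(side) < len(all_leaves) - 1:
                out.add(side)
            return fs

        for child in self.root.children:
            visit(child)
        return out


def neighbor_joining(D: DistanceMatrix) -> PhyloTree:
    """Classical neighbor joining (Saitou & Nei agglomeration with the
    Q-criterion and standard branch-length formulas).

    Ties break to the pair with the lowest original label indices.
    Negative branch-length estimates are clamped to 0 and counted.
    """
    n = len(D.labels)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    nodes: dict[int, TreeNode] = {
        i: TreeNode(label=D.labels[i]) for i in range(n)
    }
    min_idx = {i: i for i in range(n)}
    dist = {(i, j): float(D.D[i, j]) for i in range(n) for j in range(i + 1, n)}

    def get(i: int, j: int) -> float:
        return dist[(i, j) if i < j else (j, i)]

    active = list(range(n))
    next_id = n
    clamped = 0
    while len(active) > 3:
        m = len(active)
        r = {i: sum(get(i, k) for k in active if k != i) for i in active}
        best = None
        order = sorted(active, key=lambda c: min_idx[c])
        for ai in range(len(order)):
            for bi in range(ai + 1, len(order)):
                i, j = order[ai], order[bi]
                q = (m - 2) * get(i, j) - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, f, g = best
        d_fg = get(f, g)
        lf = 0.5 * d_fg + (r[f] - r[g]) / (2.0 * (m - 2))
        lg = d_fg - lf
        if lf < 0:
            clamped += 1
            lf = 0.0
        if lg < 0:
            clamped += 1
            lg = 0.0
        nodes[f].edge_length = lf
        nodes[g].edge_length = lg
        new = TreeNode(children=[nodes[f], nodes[g]])
        u = next_id
        next_id += 1
        for k in active:
            if k in (f, g):
                continue
            dku = 0.5 * (get(f, k) + get(g, k) - d_fg)
            dist[(k, u) if k < u else (u, k)] = dku
        active = [k for k in active if k not in (f, g)] + [u]
        nodes[u] = new
        min_idx[u] = min(min_idx[f], min_idx[g])
    # join the last three nodes at an unrooted central node
    i, j, k = sorted(active, key=lambda c: min_idx[c])
    li = 0.5 * (get(i, j) + get(i, k) - get(j, k))
    lj = 0.5 * (get(i, j) + get(j, k) - get(i, k))
    lk = 0.5 * (get(i, k) + get(j, k) - get(i, j))
    lengths = []
    for lv in (li, lj, lk):
        if lv < 0:
            clamped += 1
            lv = 0.0
        lengths.append(lv)
    for node, lv in zip((nodes[i], nodes[j], nodes[k]), lengths):
        node.edge_length = lv
    root = TreeNode(children=[nodes[i], nodes[j], nodes[k]])
    return PhyloTree(root=root, labels=list(D.labels), negative_branches_clamped=clamped)


def _tree_splits(tree: Dendrogram | PhyloTree, leaves: frozenset[str]) -> set[frozenset[str]]:
    """Canonical non-trivial bipartitions of either tree kind."""
    if isinstance(tree, PhyloTree):
        return tree.splits()
    anchor = sorted(leaves)[0]
    out = set()
    for clade in tree.clades():
        side = clade if anchor not in clade else leaves - clade
        if 1 < len(side) < len(leaves) - 1:
            out.add(side)
    return out


def robinson_foulds(t1: Dendrogram | PhyloTree, t2: Dendrogram | PhyloTree) -> int:
    """Robinson-Foulds distance: size of the symmetric difference of the
    two trees' non-trivial bipartition sets."""
    l1 = frozenset(t1.labels)
    l2 = frozenset(t2.labels)
    if l1 != l2:
        raise ValueError("trees have different leaf sets")
    s1 = _tree_splits(t1, l1)
    s2 = _tree_splits(t2, l1)
    return len(s1 ^ s2)


def _is_monophyletic(
    tree: Dendrogram | PhyloTree, group: frozenset[str], leaves: frozenset[str]
) -> bool:
    if len(group) <= 1 or group == leaves:
        return True
    if len(group) == len(leaves) - 1:
        # trivial split: always displayed by an unrooted tree
        if isinstance(tree, PhyloTree):
            return True
    if isinstance(tree, Dendrogram):
        return group in tree.clades()
    # unrooted: monophyletic iff some edge splits exactly this group off
    anchor = sorted(leaves)[0]
    side = group if anchor not in group else leaves - group
    return side in tree.splits() or len(side) == 1


@dataclass
class CongruenceReport:
    class_monophyly: pd.DataFrame
    n_classes_seq_only: int
    robinson_foulds: int

    def to_text(self) -> str:
        lines = ["class monophyly (ms_tree / seq_tree):"]
        for row in self.class_monophyly.itertuples():
            lines.append(
                f"  {row.group}: ms={'yes' if row.monophyletic_ms else 'no'}"
                f" seq={'yes' if row.monophyletic_seq else 'no'}"
            )
        lines.append(
            f"classes monophyletic in seq tree but not ms tree: {self.n_classes_seq_only}"
        )
        lines.append(f"Robinson-Foulds distance: {self.robinson_foulds}")
        return "\n".join(lines)


def compare_partitions(
    ms_tree: Dendrogram,
    seq_tree: PhyloTree,
    strain_to_class: dict[str, str],
) -> CongruenceReport:
    """Compare taxonomic organization of the spectrum-based dendrogram and
    the sequence-based tree: per-class monophyly in each, the count of
    classes resolved only by the sequence tree, and the RF distance."""
    leaves = frozenset(ms_tree.labels)
    if leaves != frozenset(seq_tree.labels):
        raise ValueError("trees have different leaf sets")
    missing = leaves - set(strain_to_class)
    if missing:
        raise ValueError(f"no class assigned for: {sorted(missing)}")
    classes: dict[str, set[str]] = {}
    for strain, cls in strain_to_class.items():
        if strain in leaves:
            classes.setdefault(cls, set()).add(strain)
    rows = []
    seq_only = 0
    for cls in sorted(classes):
        group = frozenset(classes[cls])
        mono_ms = _is_monophyletic(ms_tree, group, leaves)
        mono_seq = _is_monophyletic(seq_tree, group, leaves)
        if mono_seq and not mono_ms:
            seq_only += 1
        rows.append(
            {"group": cls, "monophyletic_ms": mono_ms, "monophyletic_seq": mono_seq}
        )
    return CongruenceReport(
        class_monophyly=pd.DataFrame(rows),
        n_classes_seq_only=seq_only,
        robinson_foulds=robinson_foulds(ms_tree, seq_tree),
    )
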
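"""Fingerprint similarity (Pearson on binned profiles), UPGMA dendrograms,
and pseudo-gel rendering."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import ProfileSpectrum


@dataclass
class TreeNode:
    """A rooted tree node; leaves carry a label, internal nodes a height
    (dendrograms) and/or edge length to the parent (phylogenies)."""

    label: str | None = None
    children: list["TreeNode"] = field(default_factory=list)
    height: float = 0.0
    edge_length: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_labels(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaf_labels())
        return out

    def to_newick(self, lengths_from_heights: bool = False) -> str:
        def render(node: TreeNode, parent_height: float | None) -> str:
            if node.is_leaf:
                core = _quote_label(node.label)
            else:
                core = "(" + ",".join(render(c, node.height) for c in node.children) + ")"
            if lengths_from_heights and parent_height is not None:
                return f"{core}:{parent_height - node.height:.10g}"
            if node.edge_length is not None:
                return f"{core}:{node.edge_length:.10g}"
            return core

        return render(self, None) + ";"


def _quote_label(label: str) -> str:
    if any(ch in label for ch in " (),:;'[]"):
        return "'" + label.replace("'", "''") + "'"
    return label


@dataclass
class SimilarityMatrix:
    labels: list[str]
    S: np.ndarray

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        n = len(self.labels)
        if self.S.shape != (n, n):
            raise ValueError("similarity matrix shape does not match labels")
        if not np.allclose(self.S, self.S.T, atol=1e-10):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(self.S), 1.0, atol=1e-10):
            raise ValueError("similarity matrix diagonal must be 1")
        if self.S.min() < -1 - 1e-10 or self.S.max() > 1 + 1e-10:
            raise ValueError("similarities must lie in [-1, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.S, index=self.labels, columns=self.labels)


@dataclass
class Dendrogram:
    """UPGMA output: a rooted binary merge tree with non-decreasing heights."""

    root: TreeNode
    labels: list[str]

    def to_newick(self) -> str:
        return self.root.to_newick(lengths_from_heights=True)

    def n_merges(self) -> int:
        def count(node: TreeNode) -> int:
            return 0 if node.is_leaf else 1 + sum(count(c) for c in node.children)

        return count(self.root)

    def cophenetic_matrix(self) -> pd.DataFrame:
        """Pairwise cophenetic distances: 2 x the merge height at which
        two leaves first share a cluster."""
        n = len(self.labels)
        idx = {lab: i for i, lab in enumerate(self.labels)}
        D = np.zeros((n, n))

        def visit(node: TreeNode) -> list[str]:
            if node.is_leaf:
                return [node.label]
            groups = [visit(c) for c in node.children]
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for a in groups[gi]:
                        for b in groups[gj]:
                            D[idx[a], idx[b]] = D[idx[b], idx[a]] = 2.0 * node.height
            return [lab for g in groups for lab in g]

        visit(self.root)
        return pd.DataFrame(D, index=self.labels, columns=self.labels)

    def clades(self) -> set[frozenset[str]]:
        out: set[frozenset[str]] = set()

        def visit(node: TreeNode) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.label])
            fs = frozenset().union(*(visit(c) for c in node.children))
            out.add(fs)
            return fs

        visit(self.root)
        return out


def parse_newick(text: str) -> TreeNode:
    """Parse a Newick string into a TreeNode (labels and branch lengths)."""
    text = text.strip()
    if text.endswith(";"):
        text = text[:-1]
    pos = 0

    def parse_node() -> TreeNode:
        nonlocal pos
        node = TreeNode()
        if pos < len(text) and text[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_node())
                if pos >= len(text):
                    raise ValueError("unbalanced parentheses in Newick string")
                if text[pos] == ",":
                    pos += 1
                    continue
                if text[pos] == ")":
                    pos += 1
                    break
        # label
        start = pos
        if pos < len(text) and text[pos] == "'":
            pos += 1
            label_chars = []
            while pos < len(text):
                if text[pos] == "'" and pos + 1 < len(text) and text[pos + 1] == "'":
                    label_chars.append("'")
                    pos += 2
                elif text[pos] == "'":
                    pos += 1
                    break
                else:
                    label_chars.append(text[pos])
                    pos += 1
            node.label = "".join(label_chars)
        else:
            while pos < len(text) and text[pos] not in ",():;":
                pos += 1
            if pos > start:
                node.label = text[start:pos]
        if node.label and ":" in node.label:
            node.label = node.label.split(":")[0] or None
            pos = start + (len(node.label) if node.label else 0)
        if pos < len(text) and text[pos] == ":":
            pos += 1
            start = pos
            while pos < len(text) and text[pos] not in ",()":
                pos += 1
            node.edge_length = float(text[start:pos])
        return node

    root = parse_node()
    if pos != len(text):
        raise ValueError("trailing characters in Newick string")
    return root


def grid_centers(lo: float, hi: float, bin_width: float) -> np.ndarray:
    n_bins = math.ceil((hi - lo) / bin_width)
    return lo + (np.arange(n_bins) + 0.5) * bin_width


def resample_to_grid(
    s: ProfileSpectrum,
    bin_width: float = 3.0,
    mass_window: tuple[float, float] | None = None,
) -> np.ndarray:
    """Mean intensity per fixed-width bin spanning the mass window;
    empty bins are 0. Vector length = ceil((hi - lo) / bin_width)."""
    lo, hi = mass_window if mass_window is not None else s.mass_window
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if bin_width >= hi - lo:
        raise ValueError("bin_width must be smaller than the window span")
    n_bins = math.ceil((hi - lo) / bin_width)
    idx = np.floor((s.mz - lo) / bin_width).astype(int)
    keep = (idx >= 0) & (idx < n_bins)
    idx = idx[keep]
    vals = s.intensity[keep]
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins)
    np.add.at(sums, idx, vals)
    np.add.at(counts, idx, 1)
    out = np.zeros(n_bins)
    nonempty = counts > 0
    out[nonempty] = sums[nonempty] / counts[nonempty]
    return out


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(np.sqrt(np.sum(xc * xc)))
    sy = float(np.sqrt(np.sum(yc * yc)))
    if sx == 0 or sy == 0:
        raise ValueError("zero variance")
    r = float(np.dot(xc, yc) / (sx * sy))
    return max(-1.0, min(1.0, r))


def similarity_matrix(
    fingerprints: list[np.ndarray], labels: list[str]
) -> SimilarityMatrix:
    if len(fingerprints) < 2:
        raise ValueError("need >= 2 fingerprints")
    if len(fingerprints) != len(labels):
        raise ValueError("labels/fingerprints count mismatch")
    n = len(fingerprints)
    S = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            S[i, j] = S[j, i] = pearson(fingerprints[i], fingerprints[j])
    return SimilarityMatrix(labels=list(labels), S=S)


def upgma(sim: SimilarityMatrix) -> Dendrogram:
    """Average-linkage (UPGMA) agglomeration of d = 1 - S.

    Merge height is half the average inter-cluster distance (the classical
    convention, making cophenetic distance = that average). Ties break to
    the pair with the lowest original label indices.
    """
    n = len(sim.labels)
    if n < 2:
        raise ValueError("need >= 2 items to cluster")
    D = 1.0 - sim.S
    # active clusters: id -> (node, size, min original index)
    nodes: dict[int, TreeNode] = {
        i: TreeNode(label=sim.labels[i], height=0.0) for i in range(n)
    }
    sizes = {i: 1 for i in range(n)}
    min_idx = {i: i for i in range(n)}
    dist: dict[tuple[int, int], float] = {
        (i, j): float(D[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    next_id = n
    active = set(range(n))
    while len(active) > 1:
        # pick minimal distance; ties by lowest (min original index) pair
        best = None
        for i in sorted(active, key=lambda c: min_idx[c]):
            for j in sorted(active, key=lambda c: min_idx[c]):
                if min_idx[i] >= min_idx[j]:
                    continue
                key = (i, j) if i < j else (j, i)
                d = dist[key]
                if best is None or d < best[0] - 1e-15:
                    best = (d, i, j)
        d, a, b = best
        new_node = TreeNode(children=[nodes[a], nodes[b]], height=d / 2.0)
        new_size = sizes[a] + sizes[b]
        # Lance-Williams average-linkage update
        new_dists = {}
        for c in active:
            if c in (a, b):
                continue
            ka = (a, c) if a < c else (c, a)
            kb = (b, c) if b < c else (c, b)
            new_dists[c] = (sizes[a] * dist[ka] + sizes[b] * dist[kb]) / new_size
        active.discard(a)
        active.discard(b)
        cid = next_id
        next_id += 1
        nodes[cid] = new_node
        sizes[cid] = new_size
        min_idx[cid] = min(min_idx[a], min_idx[b])
        for c, dv in new_dists.items():
            key = (c, cid) if c < cid else (cid, c)
            dist[key] = dv
        active.add(cid)
    root = nodes[active.pop()]
    return Dendrogram(root=root, labels=list(sim.labels))


def pseudo_gel(
    fingerprints: list[np.ndarray],
    labels: list[str],
    out_path: str,
    mass_window: tuple[float, float] = (2000.0, 20000.0),
    bin_width: float = 3.0,
) -> None:
    """Render a gel-electrophoresis-style image: one horizontal lane per
    sample, band darkness monotone in intensity."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if len(fingerprints) != len(labels):
        raise ValueError("labels/fingerprints count mismatch")
    mat = np.zeros((len(fingerprints), len(fingerprints[0])))
    for i, fp in enumerate(fingerprints):
        peak = float(np.max(fp)) if len(fp) and np.max(fp) > 0 else 1.0
        mat[i] = np.asarray(fp, dtype=float) / peak
    lo, hi = mass_window
    fig, ax = plt.subplots(figsize=(8, 0.6 * max(1, len(labels)) + 1.2))
    ax.imshow(
        mat,
        aspect="auto",
        cmap="Greys",
        vmin=0.0,
        vmax=1.0,
        interpolation="nearest",
        extent=(lo, lo + mat.shape[1] * bin_width, len(labels) - 0.5, -0.5),
    )
    ax.set_yticks(range(len(labels)))
    ax.set_yticklabels(labels)
    ax.set_xlabel("m/z")
    fig.tight_layout()
    fig.savefig(out_path, dpi=100)
    plt.close(fig)
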
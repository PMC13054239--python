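"""Alignment, neighbor-joining and the method-clustering audit.

The barcodes entering the tree are near-identical within species and
free of true indels, so the multiple alignment is built by anchored
stacking: every sequence is aligned pairwise to a common reference (by
default the longest input) and its bases are projected onto reference
coordinates.  This yields the column-homologous alignment that a
progressive aligner would produce at these identity levels, with a fixed
column count.

Trees are built with canonical Saitou-Nei neighbor joining on
p-distances (pairwise deletion of gaps/ambiguities, transitions and
transversions both counted) and assessed with nonparametric bootstrap
over alignment columns.  The audit asks two questions of the tree: do
the barcodes of each specimen cluster together, and does any sizeable
clade consist of a single collection method (which would indicate that
the collection method, not the organism, structures the tree)?
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core_model import MethodLabel, sample_display
from .qc_metrics import UndefinedDistanceError, align_pair

__all__ = [
    "Alignment",
    "Node",
    "TreeResult",
    "build_msa",
    "distance_matrix",
    "nj_tree",
    "bootstrap",
    "audit_clustering",
    "midpoint_newick",
]


# ---------------------------------------------------------------------------
# alignment


@dataclass
class Alignment:
    labels: list
    rows: list  # gapped sequences, all equal length

    @property
    def n_positions(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def __len__(self) -> int:
        return len(self.rows)


def build_msa(seqs, labels=None, reference: Optional[str] = None) -> Alignment:
    """Reference-anchored stacking MSA.

    Each sequence is aligned (global, free end gaps) to the reference
    and projected onto reference coordinates; insertions relative to the
    reference are dropped (they are single-base artifacts at these
    identity levels).  ``n_positions`` always equals the reference
    length.
    """
    seqs = [s.upper() for s in seqs]
    if labels is None:
        labels = [f"seq{i}" for i in range(len(seqs))]
    if len(seqs) < 2:
        raise ValueError("an alignment needs at least 2 sequences")
    if reference is None:
        reference = max(seqs, key=len)
    rows = []
    for s in seqs:
        if s == reference:
            rows.append(s + "-" * (len(reference) - len(s)))
            continue
        ga, gb = align_pair(reference, s)
        row = ["-"] * len(reference)
        ri = 0
        for a, b in zip(ga, gb):
            if a != "-":
                if b != "-":
                    row[ri] = b
                ri += 1
        rows.append("".join(row))
    return Alignment(labels=list(labels), rows=rows)


_ENC = {"A": 0, "C": 1, "G": 2, "T": 3}


def _encode(aln: Alignment) -> np.ndarray:
    X = np.full((len(aln), aln.n_positions), -1, dtype=np.int8)
    for i, row in enumerate(aln.rows):
        for j, b in enumerate(row):
            X[i, j] = _ENC.get(b, -1)
    return X


def distance_matrix(aln: Alignment, on_undefined: str = "raise") -> np.ndarray:
    """p-distance matrix with pairwise deletion.

    ``on_undefined``: "raise" names the offending pair; "max" substitutes
    0.75 (used inside bootstrap replicates where a resample may drop all
    comparable columns for one pair).
    """
    X = _encode(aln)
    return _distances_from_encoding(X, aln.labels, on_undefined)


def _distances_from_encoding(X: np.ndarray, labels, on_undefined: str) -> np.ndarray:
    n = X.shape[0]
    D = np.zeros((n, n))
    valid_rows = X >= 0
    for i in range(n - 1):
        valid = valid_rows[i] & valid_rows[i + 1 :]
        denom = valid.sum(axis=1)
        diff = ((X[i] != X[i + 1 :]) & valid).sum(axis=1)
        if (denom == 0).any():
            if on_undefined == "raise":
                j = int(np.flatnonzero(denom == 0)[0]) + i + 1
                raise UndefinedDistanceError(
                    f"no comparable sites between {labels[i]!r} and {labels[j]!r}"
                )
            d = np.where(denom == 0, 0.75, diff / np.maximum(denom, 1))
        else:
            d = diff / denom
        D[i, i + 1 :] = D[i + 1 :, i] = d
    return D


# ---------------------------------------------------------------------------
# neighbor joining


@dataclass
class Node:
    label: Optional[str] = None
    children: list = field(default_factory=list)  # (Node, branch_length)
    support: Optional[float] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> frozenset:
        # iterative: NJ trees can be deep enough to break recursion
        out = []
        stack = [self]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.append(node.label)
            else:
                stack.extend(c for c, _ in node.children)
        return frozenset(out)

    def newick(self, show_support: bool = True, min_support: Optional[float] = None) -> str:
        import sys

        limit = sys.getrecursionlimit()
        sys.setrecursionlimit(max(limit, 20000))
        try:
            return self._nwk(show_support, min_support) + ";"
        finally:
            sys.setrecursionlimit(limit)

    def _nwk(self, show_support, min_support) -> str:
        if self.is_leaf:
            return f"'{self.label}'" if any(c in self.label for c in " (),:;") else self.label
        inner = ",".join(
            f"{c._nwk(show_support, min_support)}:{bl:.6g}" for c, bl in self.children
        )
        lab = ""
        if show_support and self.support is not None:
            if min_support is None or self.support > min_support:
                lab = f"{self.support:g}"
        return f"({inner}){lab}"


@dataclass
class TreeResult:
    root: Node
    labels: list
    distances: np.ndarray
    supports: dict = field(default_factory=dict)  # canonical bipartition -> %
    audit: dict = field(default_factory=dict)

    def newick(self, min_support: Optional[float] = None) -> str:
        return self.root.newick(min_support=min_support)

    def bipartition_sides(self) -> list[frozenset]:
        """Every clade leaf set induced by an edge, in both orientations."""
        all_leaves = self.root.leaves()
        sides = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            for child, _ in node.children:
                ls = child.leaves()
                sides.append(ls)
                sides.append(all_leaves - ls)
                stack.append(child)
        return sides

    def internal_bipartitions(self) -> set[frozenset]:
        n = len(self.labels)
        return {
            _canonical(s, self.labels)
            for s in self.bipartition_sides()
            if 2 <= len(s) <= n - 2
        }


def _canonical(side: frozenset, labels) -> frozenset:
    """Orientation-free bipartition key: the side NOT holding the first label."""
    anchor = min(labels)
    full = frozenset(labels)
    return full - side if anchor in side else side


def nj_tree(aln_or_D, labels=None) -> TreeResult:
    """Canonical Saitou-Nei neighbor joining.

    Accepts an :class:`Alignment` (p-distances computed with pairwise
    deletion) or a precomputed distance matrix plus labels.  Q-matrix
    ties break toward the lexicographically lowest label pair; negative
    branch lengths are clamped to zero with the deficit moved to the
    sister edge so the pair distance is preserved.
    """
    if isinstance(aln_or_D, Alignment):
        labels = list(aln_or_D.labels)
        D = distance_matrix(aln_or_D)
    else:
        D = np.array(aln_or_D, dtype=float)
        labels = list(labels)
    n0 = len(labels)
    if n0 < 2:
        raise ValueError("need at least 2 taxa")
    if len(set(labels)) != n0:
        raise ValueError("labels must be unique")

    nodes = [Node(label=l) for l in labels]
    names = list(labels)  # min leaf label per cluster, for tie-breaking
    D = D.copy()

    def clamp_pair(li, lj):
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(nodes) > 3:
        n = len(nodes)
        r = D.sum(axis=0)
        Q = (n - 2) * D - r[:, None] - r[None, :]
        Q = 0.5 * (Q + Q.T)  # exact symmetry so ties appear in both orientations
        np.fill_diagonal(Q, np.inf)
        cands = np.argwhere(Q == Q.min())
        i, j = min(
            {(int(min(a, b)), int(max(a, b))) for a, b in cands},
            key=lambda ij: tuple(sorted((names[ij[0]], names[ij[1]]))),
        )
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (n - 2))
        lj = D[i, j] - li
        li, lj = clamp_pair(li, lj)
        new = Node(children=[(nodes[i], li), (nodes[j], lj)])
        dnew = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        D2 = np.zeros((len(keep) + 1, len(keep) + 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = np.maximum(dnew[keep], 0.0)
        nodes = [nodes[k] for k in keep] + [new]
        names = [names[k] for k in keep] + [min(names[i], names[j])]
        D = D2

    if len(nodes) == 3:
        l0 = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
        l1 = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
        l2 = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
        root = Node(children=[(nodes[k], max(l, 0.0)) for k, l in zip(range(3), (l0, l1, l2))])
    else:
        half = D[0, 1] / 2.0
        root = Node(children=[(nodes[0], half), (nodes[1], half)])

    if isinstance(aln_or_D, Alignment):
        dist = distance_matrix(aln_or_D)
    else:
        dist = np.array(aln_or_D, dtype=float)
    return TreeResult(root=root, labels=labels, distances=dist)


def bootstrap(aln: Alignment, reps: int = 10000, seed: int = 0,
              tree: Optional[TreeResult] = None) -> TreeResult:
    """Column-resampling bootstrap: support of each original bipartition is
    the % of replicate NJ trees containing it.

    The full default (10,000 replicates) matches barcoding practice;
    tests and the packaged examples run scaled-down replicate counts.
    """
    if tree is None:
        tree = nj_tree(aln)
    targets = tree.internal_bipartitions()
    counts = {bp: 0 for bp in targets}
    rng = np.random.default_rng(seed)
    X = _encode(aln)
    L = X.shape[1]
    for _ in range(reps):
        cols = rng.integers(0, L, size=L)
        Drep = _distances_from_encoding(X[:, cols], aln.labels, on_undefined="max")
        rep_tree = nj_tree(Drep, aln.labels)
        rep_bps = rep_tree.internal_bipartitions()
        for bp in targets:
            if bp in rep_bps:
                counts[bp] += 1
    tree.supports = {bp: 100.0 * c / reps for bp, c in counts.items()} if reps else {}
    _annotate_supports(tree)
    return tree


def _annotate_supports(tree: TreeResult) -> None:
    n = len(tree.labels)
    stack = [tree.root]
    while stack:
        node = stack.pop()
        for child, _ in node.children:
            ls = child.leaves()
            if 2 <= len(ls) <= n - 2:
                bp = _canonical(ls, tree.labels)
                if bp in tree.supports:
                    child.support = tree.supports[bp]
            stack.append(child)


# ---------------------------------------------------------------------------
# audit


def audit_clustering(tree: TreeResult, min_pure_clade: int = 4) -> dict:
    """Method-clustering audit of the barcode tree.

    (a) For every specimen with >= 2 barcodes: do its barcodes form a
    clade?  Specimens whose barcodes are interleaved only with
    zero-distance (identical) sequences are reported separately.
    (b) For every collection method: does any clade of
    ``min_pure_clade`` or more barcodes consist purely of that method?
    Any such clade raises a method-clustering warning.

    Leaf labels must follow the "<specimen> <Method>" display form.
    """
    sides = tree.bipartition_sides()
    side_set = set(sides)
    idx = {l: k for k, l in enumerate(tree.labels)}

    by_specimen: dict[str, set] = {}
    method_of: dict[str, str] = {}
    for label in tree.labels:
        specimen, method = label.rsplit(" ", 1)
        by_specimen.setdefault(specimen, set()).add(label)
        method_of[label] = method

    specimen_verdicts = {}
    for specimen, group in by_specimen.items():
        if len(group) < 2:
            continue
        fg = frozenset(group)
        if fg in side_set:
            specimen_verdicts[specimen] = "monophyletic"
            continue
        containing = [s for s in sides if fg <= s]
        smallest = min(containing, key=len)
        extras = smallest - fg
        zero = all(
            tree.distances[idx[e], idx[m]] == 0.0 for e in extras for m in group
        )
        specimen_verdicts[specimen] = (
            "monophyletic_with_identical_sequences" if zero else "not_monophyletic"
        )

    method_warnings = []
    for s in sides:
        if len(s) >= min_pure_clade and len(s) < len(tree.labels):
            methods = {method_of[l] for l in s}
            if len(methods) == 1:
                method_warnings.append(
                    {"method": methods.pop(), "clade_size": len(s), "labels": sorted(s)}
                )

    verdict_counts = {
        v: sum(1 for x in specimen_verdicts.values() if x == v)
        for v in set(specimen_verdicts.values())
    }
    audit = {
        "specimen_verdicts": specimen_verdicts,
        "specimen_verdict_counts": verdict_counts,
        "method_pure_clades": method_warnings,
        "method_clustering_detected": bool(method_warnings),
    }
    tree.audit = audit
    return audit


def midpoint_newick(newick: str) -> str:
    """Midpoint-rooted rendering of a newick tree (display only)."""
    import dendropy

    t = dendropy.Tree.get(data=newick, schema="newick")
    t.reroot_at_midpoint(update_bipartitions=False)
    return t.as_string(schema="newick").strip()
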
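"""MSA stacking, neighbor joining (with an exhaustive least-squares
oracle), bootstrap and the clustering audit."""

import itertools

import numpy as np
import pytest
from scipy.optimize import nnls

from wormcoi.cluster_tree import (
    Alignment,
    TreeResult,
    audit_clustering,
    bootstrap,
    build_msa,
    distance_matrix,
    nj_tree,
)
from wormcoi.qc_metrics import UndefinedDistanceError
from wormcoi.synthetic_data import generate_haplotype, inject_substitutions


# ---------------------------------------------------------------------------
# exhaustive topology oracle


def _enumerate_topologies(labels):
    """All unrooted binary topologies over `labels`, each as the set of
    its internal bipartitions.  Built by inserting every leaf on every
    edge of every smaller topology (3 -> 1 tree, 4 -> 3, 5 -> 15, ...)."""
    l0, l1, l2, *rest = labels
    trees = [[(l0, "i0"), (l1, "i0"), (l2, "i0")]]
    for k, leaf in enumerate(rest):
        new_node = f"i{k + 1}"
        grown = []
        for edges in trees:
            for idx, (u, v) in enumerate(edges):
                grown.append(
                    edges[:idx] + edges[idx + 1 :]
                    + [(u, new_node), (v, new_node), (leaf, new_node)]
                )
        trees = grown

    leafset = set(labels)
    out, seen = [], set()
    for edges in trees:
        adj: dict = {}
        for u, v in edges:
            adj.setdefault(u, []).append(v)
            adj.setdefault(v, []).append(u)
        bps = set()
        for u, v in edges:
            visited = {u, v}
            stack, side = [v], set()
            while stack:
                x = stack.pop()
                if x in leafset:
                    side.add(x)
                for y in adj[x]:
                    if y not in visited:
                        visited.add(y)
                        stack.append(y)
            if 2 <= len(side) <= len(labels) - 2:
                bps.add(frozenset(side))
        key = frozenset(bps)
        if key not in seen:
            seen.add(key)
            out.append(bps)
    return out


def _ls_fit(bipartitions, labels, D):
    """Least-squares branch lengths for a topology; returns RSS."""
    n = len(labels)
    idx = {l: i for i, l in enumerate(labels)}
    full = frozenset(labels)
    edges = [frozenset([l]) for l in labels] + list(bipartitions)
    pairs = list(itertools.combinations(labels, 2))
    A = np.zeros((len(pairs), len(edges)))
    y = np.zeros(len(pairs))
    for r, (a, b) in enumerate(pairs):
        y[r] = D[idx[a], idx[b]]
        for c, e in enumerate(edges):
            if (a in e) != (b in e):
                A[r, c] = 1.0
    x, _ = nnls(A, y)
    return float(((A @ x - y) ** 2).sum())


def _random_additive(labels, rng):
    """Random binary topology + positive branch lengths -> additive D."""
    # random sequential joining yields a random topology
    children: dict = {}
    active = [frozenset([l]) for l in labels]
    while len(active) > 3:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[int(j)], active[int(i)]
        active = [x for x in active if x not in (a, b)] + [a | b]
        children[a | b] = (a, b)
    # collect internal bipartitions
    bps = [s for s in children if 2 <= len(s) <= len(labels) - 2]
    edges = [frozenset([l]) for l in labels] + bps
    lengths = {e: rng.uniform(0.05, 0.3) for e in edges}
    n = len(labels)
    D = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i < j:
                d = sum(
                    w for e, w in lengths.items() if (a in e) != (b in e)
                )
                D[i, j] = D[j, i] = d
    return D, frozenset(frozenset(s) for s in bps)


class TestBuildMsa:
    def test_identical_sequences_gap_free(self):
        seq = generate_haplotype(1)
        aln = build_msa([seq, seq, seq])
        assert aln.n_positions == len(seq)
        assert all(row == seq for row in aln.rows)

    def test_terminal_truncation_gives_terminal_gaps(self):
        seq = generate_haplotype(2)
        aln = build_msa([seq, seq[:-3]], labels=["a", "b"])
        assert aln.rows[1] == seq[:-3] + "---"

    def test_fewer_than_two_sequences_rejected(self):
        with pytest.raises(ValueError):
            build_msa([generate_haplotype(3)])


class TestNeighborJoining:
    def test_four_taxon_additive_example(self):
        # d(AB)=0.2, d(CD)=0.2, all cross distances 0.5 -> ((A,B),(C,D))
        labels = ["A", "B", "C", "D"]
        D = np.array([
            [0.0, 0.2, 0.5, 0.5],
            [0.2, 0.0, 0.5, 0.5],
            [0.5, 0.5, 0.0, 0.2],
            [0.5, 0.5, 0.2, 0.0],
        ])
        tree = nj_tree(D, labels)
        assert tree.internal_bipartitions() == {frozenset({"C", "D"})}

    def test_three_taxon_closed_form(self):
        labels = ["A", "B", "C"]
        D = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.4], [0.5, 0.4, 0.0]])
        tree = nj_tree(D, labels)
        lengths = {c.label: bl for c, bl in tree.root.children}
        assert lengths["A"] == pytest.approx(0.2)
        assert lengths["B"] == pytest.approx(0.1)
        assert lengths["C"] == pytest.approx(0.3)

    def test_duplicate_sequences_zero_length_cherry(self):
        seq = generate_haplotype(7)
        other = inject_substitutions(seq, 0.2, np.random.default_rng(0))
        third = inject_substitutions(seq, 0.2, np.random.default_rng(1))
        labels = ["a1", "a2", "b", "c"]
        aln = build_msa([seq, seq, other, third], labels=labels)
        tree = nj_tree(aln)
        from wormcoi.cluster_tree import _canonical

        assert _canonical(frozenset({"a1", "a2"}), labels) in tree.internal_bipartitions()
        # the cherry over the duplicates has zero-length pendant edges
        def find(node):
            for c, bl in node.children:
                if c.leaves() == frozenset({"a1", "a2"}):
                    return c
                got = find(c)
                if got:
                    return got
        cherry = find(tree.root)
        assert all(bl == 0.0 for _, bl in cherry.children)

    def test_negative_branch_clamping_preserves_pair_distance(self):
        # a matrix known to produce a negative NJ branch
        labels = ["A", "B", "C", "D"]
        D = np.array([
            [0.0, 0.1, 0.4, 0.45],
            [0.1, 0.0, 0.05, 0.5],
            [0.4, 0.05, 0.0, 0.3],
            [0.45, 0.5, 0.3, 0.0],
        ])
        tree = nj_tree(D, labels)

        def all_lengths(node):
            for c, bl in node.children:
                yield bl
                yield from all_lengths(c)

        assert all(bl >= 0 for bl in all_lengths(tree.root))

    @pytest.mark.parametrize("n_taxa", [4, 5, 6])
    def test_additive_matrices_match_least_squares_oracle(self, n_taxa):
        labels = [f"T{i}" for i in range(n_taxa)]
        rng = np.random.default_rng(100 + n_taxa)
        for trial in range(5):
            D, true_bps = _random_additive(labels, rng)
            tree = nj_tree(D, labels)
            got = tree.internal_bipartitions()
            # canonicalize both against the anchor convention
            from wormcoi.cluster_tree import _canonical

            want = {_canonical(bp, labels) for bp in true_bps}
            assert got == want
            # oracle: exhaustive least-squares over all topologies
            best_rss, best_topo = np.inf, None
            for bps in _enumerate_topologies(labels):
                rss = _ls_fit(bps, labels, D)
                if rss < best_rss - 1e-12:
                    best_rss, best_topo = rss, bps
            assert {_canonical(bp, labels) for bp in best_topo} == want

    def test_undefined_distance_names_the_pair(self):
        aln = Alignment(labels=["x", "y"], rows=["NNNN", "ACGT"])
        with pytest.raises(UndefinedDistanceError, match="x"):
            distance_matrix(aln)


class TestBootstrap:
    def _two_cluster_alignment(self):
        a = generate_haplotype(11)
        b = inject_substitutions(a, 0.3, np.random.default_rng(3))
        labels = ["a1", "a2", "a3", "b1", "b2", "b3"]
        return build_msa([a, a, a, b, b, b], labels=labels)

    def test_separated_clusters_full_support(self):
        aln = self._two_cluster_alignment()
        tree = bootstrap(aln, reps=200, seed=9)
        bp = frozenset({"b1", "b2", "b3"})
        from wormcoi.cluster_tree import _canonical

        assert tree.supports[_canonical(bp, aln.labels)] == 100.0
        assert all(0.0 <= s <= 100.0 for s in tree.supports.values())

    def test_same_seed_identical_supports(self):
        aln = self._two_cluster_alignment()
        t1 = bootstrap(aln, reps=50, seed=4)
        t2 = bootstrap(aln, reps=50, seed=4)
        assert t1.supports == t2.supports


class TestAudit:
    def test_specimen_monophyly_and_no_method_clustering(self):
        a = generate_haplotype(21)
        b = inject_substitutions(a, 0.25, np.random.default_rng(5))
        labels = [
            "DE1 Tissue-Chelex", "DE1 Tissue-QIAGEN",
            "DE2 Tissue-Chelex", "DE2 Swab-QIAGEN",
        ]
        aln = build_msa([a, a, b, b], labels=labels)
        tree = nj_tree(aln)
        audit = audit_clustering(tree)
        assert audit["specimen_verdicts"] == {
            "DE1": "monophyletic", "DE2": "monophyletic"
        }
        assert not audit["method_clustering_detected"]

    def test_method_pure_clade_triggers_warning(self):
        a = generate_haplotype(31)
        b = inject_substitutions(a, 0.25, np.random.default_rng(6))
        rng = np.random.default_rng(7)
        # four swab barcodes on one divergent haplotype cluster
        labels = [f"DE{i} Swab-QIAGEN" for i in range(1, 5)] + [
            f"DE{i} Tissue-Chelex" for i in range(5, 9)
        ]
        seqs = [inject_substitutions(b, 0.01, rng) for _ in range(4)] + [
            inject_substitutions(a, 0.01, rng) for _ in range(4)
        ]
        aln = build_msa(seqs, labels=labels)
        tree = nj_tree(aln)
        audit = audit_clustering(tree)
        assert audit["method_clustering_detected"]
        assert any(w["method"] == "Swab-QIAGEN" for w in audit["method_pure_clades"])

    def test_single_barcode_specimens_excluded(self):
        a = generate_haplotype(41)
        b = inject_substitutions(a, 0.25, np.random.default_rng(8))
        c = inject_substitutions(a, 0.25, np.random.default_rng(9))
        labels = ["DE1 Tissue-Chelex", "DE2 Tissue-QIAGEN", "DE3 Swab-QIAGEN",
                  "DE4 Tissue-Chelex"]
        aln = build_msa([a, b, c, inject_substitutions(a, 0.25, np.random.default_rng(10))],
                        labels=labels)
        tree = nj_tree(aln)
        audit = audit_clustering(tree)
        assert audit["specimen_verdicts"] == {}
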
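"""Allele-sharing distances and neighbor-joining reconstruction."""

import io
import itertools
import random

import dendropy
import numpy as np
import pytest

from conftest import make_snp
from ricevar import phylogeny as ph


class TestPairwiseDistance:
    def test_identical_tables_distance_zero(self):
        recs = [make_snp(pos=p, ref="A", genotype="G") for p in (10, 20, 30)]
        dm = ph.pairwise_distance({"a": recs, "b": list(recs)})
        assert dm.matrix[0, 1] == 0.0
        assert dm.n_loci_used[0, 1] == 3

    def test_definition_arithmetic_five_of_hundred(self):
        # both lines called at 100 loci; 5 homozygous-different, 95 identical
        a, b = [], []
        for i in range(100):
            pos = 10 + i
            alt_a = "G"
            alt_b = "G" if i >= 5 else "C"
            a.append(make_snp(pos=pos, ref="A", genotype=alt_a))
            b.append(make_snp(pos=pos, ref="A", genotype=alt_b))
        dm = ph.pairwise_distance({"a": a, "b": b})
        assert dm.matrix[0, 1] == pytest.approx(5 / 100)

    def test_het_overlap_scores_half_strict_scores_one(self):
        a = [make_snp(pos=10, ref="A", genotype="R")]  # {A, G}
        b = [make_snp(pos=10, ref="A", genotype="G")]
        half = ph.pairwise_distance({"a": a, "b": b})
        assert half.matrix[0, 1] == 0.5
        strict = ph.pairwise_distance({"a": a, "b": b}, metric="strict")
        assert strict.matrix[0, 1] == 1.0

    def test_absent_imputed_as_reference(self):
        a = [make_snp(pos=10, ref="A", genotype="G")]
        dm = ph.pairwise_distance({"a": a, "b": []})
        # union is one locus; b imputed {A}, disjoint from {G}
        assert dm.matrix[0, 1] == 1.0

    def test_matches_brute_force_recomputation(self):
        rng = random.Random(21)
        tables = {}
        for line in ("w", "x", "y", "z"):
            recs = []
            for pos in rng.sample(range(10, 500), 60):
                genotype = rng.choice("ACGTRYKM")
                ref = "A" if genotype != "A" else "C"
                recs.append(make_snp(pos=pos, ref=ref, genotype=genotype))
            tables[line] = recs
        # keep references consistent across lines at shared positions
        refs = {}
        for recs in tables.values():
            for r in recs:
                r.ref_base = refs.setdefault(r.pos, r.ref_base)
                if r.ref_base in r.alleles and len(r.alleles) == 1:
                    r.genotype = "G" if r.ref_base != "G" else "T"
        dm = ph.pairwise_distance(tables)
        from ricevar.records import expand_iupac
        for i, j in itertools.combinations(range(4), 2):
            li, lj = dm.labels[i], dm.labels[j]
            ai = {r.pos: r.alleles for r in tables[li]}
            aj = {r.pos: r.alleles for r in tables[lj]}
            union = set(ai) | set(aj)
            total = 0.0
            for pos in union:
                sa = ai.get(pos, frozenset({refs[pos]}))
                sb = aj.get(pos, frozenset({refs[pos]}))
                if sa == sb:
                    continue
                total += 0.5 if sa & sb else 1.0
            assert dm.matrix[i, j] == pytest.approx(total / len(union))

    def test_quality_filter_drops_low_quality_calls(self):
        a = [make_snp(pos=10, ref="A", genotype="G", quality=10),
             make_snp(pos=20, ref="A", genotype="G", quality=45)]
        b = [make_snp(pos=20, ref="A", genotype="G", quality=45)]
        dm = ph.pairwise_distance({"a": a, "b": b}, min_quality=30)
        assert dm.matrix[0, 1] == 0.0 and dm.n_loci_used[0, 1] == 1

    def test_reference_mismatch_errors(self):
        a = [make_snp(pos=10, ref="A", genotype="G")]
        b = [make_snp(pos=10, ref="C", genotype="G")]
        with pytest.raises(ValueError, match="reference mismatch"):
            ph.pairwise_distance({"a": a, "b": b})

    def test_zero_usable_loci_errors(self):
        with pytest.raises(ValueError, match="zero usable loci"):
            ph.pairwise_distance({"a": [], "b": []})

    def test_distance_invariant_under_locus_permutation(self):
        recs = [make_snp(pos=p, ref="A", genotype=g)
                for p, g in [(10, "G"), (20, "C"), (30, "T")]]
        other = [make_snp(pos=p, ref="A", genotype="G") for p in (10, 40)]
        d1 = ph.pairwise_distance({"a": recs, "b": other}).matrix[0, 1]
        d2 = ph.pairwise_distance({"a": recs[::-1], "b": other[::-1]}).matrix[0, 1]
        assert d1 == d2


def _matrix(labels, entries):
    n = len(labels)
    m = np.zeros((n, n))
    for (i, j), d in entries.items():
        m[i, j] = m[j, i] = d
    return ph.DistanceMatrix(labels=list(labels), matrix=m,
                             n_loci_used=np.full((n, n), 100))


def _tree_from_newick(text):
    return dendropy.Tree.get(data=text, schema="newick")


def _splits_with_lengths(newick, taxa):
    """{frozenset of leaf labels: branch length} for all internal + leaf edges."""
    tree = _tree_from_newick(newick)
    out = {}
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        leaves = frozenset(
            lf.taxon.label for lf in edge.head_node.leaf_iter()
        )
        side = min(leaves, frozenset(taxa) - leaves, key=lambda s: (len(s), sorted(s)))
        out[side] = out.get(side, 0.0) + (edge.length or 0.0)
    return out


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = _matrix("ABC", {(0, 1): 0.2, (0, 2): 0.3, (1, 2): 0.4})
        tree = ph.nj_tree(dm)
        lengths = {child.label: l for child, l in tree.root.children}
        assert lengths["A"] == pytest.approx(0.05)
        assert lengths["B"] == pytest.approx(0.15)
        assert lengths["C"] == pytest.approx(0.25)

    def test_four_taxon_additive_matrix_recovered_exactly(self):
        # distances from the tree ((A:1,B:2):1,(C:3,D:4)) joined by a length-1 edge
        entries = {(0, 1): 3, (0, 2): 5, (0, 3): 6, (1, 2): 6, (1, 3): 7, (2, 3): 7}
        labels = "ABCD"
        # verify additivity via the four-point condition before relying on it
        d = _matrix(labels, entries).matrix
        sums = sorted([d[0, 1] + d[2, 3], d[0, 2] + d[1, 3], d[0, 3] + d[1, 2]])
        assert sums[1] == sums[2] and sums[0] <= sums[1]
        tree = ph.nj_tree(_matrix(labels, entries))
        splits = _splits_with_lengths(ph.write_newick(tree), labels)
        assert splits[frozenset("AB")] == pytest.approx(1.0)  # internal edge
        for leaf, expect in zip("ABCD", (1, 2, 3, 4)):
            assert splits[frozenset(leaf)] == pytest.approx(expect)

    @pytest.mark.parametrize("n_taxa", [4, 5, 6, 7, 8])
    def test_random_additive_trees_recovered(self, n_taxa):
        """NJ recovers topology and branch lengths exactly from additive
        matrices derived from random trees."""
        rng = random.Random(100 + n_taxa)
        labels = [f"t{i}" for i in range(n_taxa)]
        for _ in range(5):
            true_newick, dist = _random_additive(rng, labels)
            dm = _matrix(labels, dist)
            tree = ph.nj_tree(dm)
            got = _splits_with_lengths(ph.write_newick(tree), labels)
            want = _splits_with_lengths(true_newick, labels)
            assert set(got) == set(want)
            for split in want:
                assert got[split] == pytest.approx(want[split], abs=1e-4)

    def test_permuting_line_order_gives_isomorphic_tree(self):
        entries = {(0, 1): 3, (0, 2): 5, (0, 3): 6, (1, 2): 6, (1, 3): 7, (2, 3): 7}
        base = _matrix("ABCD", entries)
        ref_splits = _splits_with_lengths(ph.write_newick(ph.nj_tree(base)), "ABCD")
        for perm in itertools.permutations(range(4)):
            labels = ["ABCD"[i] for i in perm]
            m = base.matrix[np.ix_(perm, perm)]
            dm = ph.DistanceMatrix(labels=labels, matrix=m,
                                   n_loci_used=np.full((4, 4), 1))
            splits = _splits_with_lengths(ph.write_newick(ph.nj_tree(dm)), "ABCD")
            assert splits == pytest.approx(ref_splits)

    def test_agreement_with_scikit_bio_on_additive_matrix(self):
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        entries = {(0, 1): 3, (0, 2): 5, (0, 3): 6, (1, 2): 6, (1, 3): 7, (2, 3): 7}
        dm = _matrix("ABCD", entries)
        ours = _splits_with_lengths(ph.write_newick(ph.nj_tree(dm)), "ABCD")
        sk_tree = skbio_nj(SkbioDM(dm.matrix, ids=list("ABCD")))
        theirs = _splits_with_lengths(str(sk_tree), "ABCD")
        for split, length in theirs.items():
            assert ours[split] == pytest.approx(length, abs=1e-6)

    def test_negative_branches_clamped_and_flagged(self):
        dm = _matrix("ABC", {(0, 1): 0.1, (0, 2): 0.1, (1, 2): 0.5})
        tree = ph.nj_tree(dm)
        lengths = [l for _, l in tree.root.children]
        assert min(lengths) == 0.0 and tree.clamped_branches == 1

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            ph.nj_tree(_matrix("AB", {(0, 1): 1.0}))
        with pytest.raises(ValueError, match="symmetric"):
            ph.DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0.0]]),
                              np.ones((2, 2)))
        with pytest.raises(ValueError, match="negative"):
            ph.DistanceMatrix(["a", "b"], np.array([[0, -1], [-1, 0.0]]),
                              np.ones((2, 2)))


class TestNewick:
    def test_round_trip_preserves_splits_and_lengths(self):
        entries = {(0, 1): 0.31, (0, 2): 0.52, (0, 3): 0.61,
                   (1, 2): 0.63, (1, 3): 0.72, (2, 3): 0.73}
        tree = ph.nj_tree(_matrix("ABCD", entries))
        text = ph.write_newick(tree)
        assert text.endswith(";\n")
        reparsed = _tree_from_newick(text)
        assert {lf.taxon.label for lf in reparsed.leaf_node_iter()} == set("ABCD")
        again = _splits_with_lengths(text, "ABCD")
        for split, length in _splits_with_lengths(text, "ABCD").items():
            assert again[split] == pytest.approx(length, abs=1e-6)

    def test_six_decimal_branch_formatting(self):
        dm = _matrix("ABC", {(0, 1): 0.2, (0, 2): 0.3, (1, 2): 0.4})
        text = ph.write_newick(ph.nj_tree(dm))
        assert ":0.050000" in text and ":0.250000" in text

    def test_simulated_lines_produce_a_four_leaf_tree(self, default_sim):
        cfg, _, _, lines = default_sim
        dm = ph.pairwise_distance(lines.snp_tables)
        tree = ph.nj_tree(dm)
        assert sorted(tree.root.leaves()) == sorted(cfg.line_names)
        # focal line carries ~300 private SNPs, so it cannot be the nearest
        # neighbour of any comparison line
        focal_idx = dm.labels.index(cfg.focal_name)
        others = [i for i in range(4) if i != focal_idx]
        for i in others:
            nearest = min((dm.matrix[i, j], j) for j in range(4) if j != i)[1]
            assert nearest != focal_idx


def _random_additive(rng, labels):
    """Random binary tree over labels; returns (newick, pairwise path dists)."""
    active = list(range(len(labels)))
    text = {i: labels[i] for i in active}
    leafsets = {i: [labels[i]] for i in active}
    # join random pairs with random positive branch lengths
    paths = {(a, b): 0.0 for a in labels for b in labels}
    next_id = len(labels)
    # leaf_dist[label][node id] = path length from that leaf up to the node
    leaf_dist = {labels[i]: {i: 0.0} for i in active}
    while len(active) > 1:
        i, j = rng.sample(active, 2)
        li = round(rng.uniform(0.05, 1.0), 3)
        lj = round(rng.uniform(0.05, 1.0), 3)
        for a in leafsets[i]:
            leaf_dist[a][next_id] = leaf_dist[a][i] + li
        for b in leafsets[j]:
            leaf_dist[b][next_id] = leaf_dist[b][j] + lj
        for a in leafsets[i]:
            for b in leafsets[j]:
                d = leaf_dist[a][i] + li + leaf_dist[b][j] + lj
                paths[(a, b)] = paths[(b, a)] = d
        text[next_id] = f"({text[i]}:{li},{text[j]}:{lj})"
        leafsets[next_id] = leafsets[i] + leafsets[j]
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1
    root = active[0]
    idx = {lbl: k for k, lbl in enumerate(labels)}
    entries = {
        (idx[a], idx[b]): paths[(a, b)]
        for a in labels for b in labels if idx[a] < idx[b]
    }
    return text[root] + ";", entries


def test_random_tree_generator_is_additive():
    """The helper's matrices satisfy the four-point condition, so the NJ
    recovery tests really do exercise additive inputs."""
    rng = random.Random(77)
    labels = [f"t{i}" for i in range(5)]
    _, entries = _random_additive(rng, labels)
    d = _matrix(labels, entries).matrix
    for a, b, c, e in itertools.combinations(range(5), 4):
        sums = sorted([d[a, b] + d[c, e], d[a, c] + d[b, e], d[a, e] + d[b, c]])
        assert sums[1] == pytest.approx(sums[2])
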
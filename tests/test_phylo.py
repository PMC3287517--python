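"""Nearest-reference search, distances, neighbour joining, Fitch
parsimony and placement — each checked against an independent oracle."""

import itertools
import math

import numpy as np
import pytest
from skbio import DistanceMatrix, TreeNode

from amplitag.phylo import (ReferenceRecord, align_query_to_profile, best_hit,
                            distance_matrix, fitch_score, neighbor_joining,
                            parse_newick, parsimony_place, read_newick,
                            write_newick)

BASES = list("ACGT")


def _rand_seq(rng, n=120):
    return "".join(rng.choice(BASES, size=n))


def _mut(seq, k, rng):
    out = list(seq)
    pos = rng.choice(len(seq), size=k, replace=False)
    for p in pos:
        out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
    return "".join(out)


class TestBestHit:
    def test_exact_match_wins_with_identity_one(self, rng):
        seqs = [_rand_seq(rng) for _ in range(3)]
        refs = [ReferenceRecord(f"R{i}", f"ref {i}", s) for i, s in enumerate(seqs)]
        acc, ident = best_hit(seqs[1], refs)
        assert (acc, ident) == ("R1", 1.0)

    def test_closer_reference_preferred(self, rng):
        base = "".join(rng.choice(BASES, size=450))
        near, far = _mut(base, 5, rng), _mut(base, 20, rng)
        refs = [ReferenceRecord("A", "near", near), ReferenceRecord("B", "far", far)]
        acc, ident = best_hit(base, refs)
        assert acc == "A" and ident == pytest.approx(445 / 450, abs=1e-6)

    def test_tie_broken_by_accession(self, rng):
        s = _rand_seq(rng)
        refs = [ReferenceRecord("Z9", "z", s), ReferenceRecord("A1", "a", s)]
        assert best_hit(s, refs)[0] == "A1"

    def test_empty_reference_set_rejected(self):
        with pytest.raises(ValueError):
            best_hit("ACGT", [])


class TestDistanceMatrix:
    def test_identical_sequences_zero(self, rng):
        s = _rand_seq(rng)
        dm = distance_matrix({"a": s, "b": s, "c": s}, model="p")
        assert np.allclose(dm.data, 0.0)

    def test_p_distance_definition(self, rng):
        s = _rand_seq(rng, 100)
        t = _mut(s, 2, rng)
        dm = distance_matrix({"a": s, "b": t, "c": s}, model="p")
        assert dm["a", "b"] == pytest.approx(0.02)

    def test_jc69_closed_form(self, rng):
        s = _rand_seq(rng, 100)
        t = _mut(s, 2, rng)
        dm = distance_matrix({"a": s, "b": t, "c": s}, model="jc69")
        assert dm["a", "b"] == pytest.approx(-0.75 * math.log(1 - 0.08 / 3), abs=1e-9)

    def test_gap_columns_pairwise_deleted(self):
        dm = distance_matrix(
            {"a": "ACGTACGTAC", "b": "-CGTACGTAC", "c": "ANGTACGTAC"}, model="p")
        assert dm["a", "b"] == 0.0 and dm["a", "c"] == 0.0

    def test_saturation_raises_under_jc69(self):
        with pytest.raises(ValueError, match="saturated"):
            distance_matrix({"a": "AAAA", "b": "CCCC", "c": "AAAA"}, model="jc69")


def _random_tree(rng, n_leaves):
    """Random unrooted binary tree with positive branch lengths."""
    nodes = [TreeNode(name=f"t{i}", length=float(rng.uniform(0.05, 1.0)))
             for i in range(n_leaves)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = TreeNode(length=float(rng.uniform(0.05, 1.0)), children=[a, b])
        nodes.append(parent)
    root = TreeNode(children=nodes)
    return root


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix([[0, 3, 4], [3, 0, 5], [4, 5, 0]], ["a", "b", "c"])
        tree = neighbor_joining(dm)
        lengths = {t.name: t.length for t in tree.children}
        assert lengths["a"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["b"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["c"] == pytest.approx((4 + 5 - 3) / 2)

    def test_additive_four_taxon_recovery(self):
        # tree ((a:2,b:3):1,c:4,d:5) -> path distances are additive
        d = {("a", "b"): 5, ("a", "c"): 7, ("a", "d"): 8,
             ("b", "c"): 8, ("b", "d"): 9, ("c", "d"): 9}
        labels = ["a", "b", "c", "d"]
        mat = [[0 if i == j else d[tuple(sorted((x, y)))]
                for j, y in enumerate(labels)] for i, x in enumerate(labels)]
        tree = neighbor_joining(DistanceMatrix(mat, labels))
        tt = tree.tip_tip_distances()
        for (x, y), v in d.items():
            assert tt[x, y] == pytest.approx(v, abs=1e-12)

    @pytest.mark.parametrize("n_leaves", [4, 7, 12])
    def test_recovers_random_additive_trees(self, n_leaves, rng):
        for _ in range(5):
            true = _random_tree(rng, n_leaves)
            dm = true.tip_tip_distances()
            est = neighbor_joining(dm)
            assert est.compare_rfd(true) == 0.0
            tt = est.tip_tip_distances()
            for a, b in itertools.combinations(sorted(dm.ids), 2):
                assert abs(tt[a, b] - dm[a, b]) < 1e-9

    def test_agrees_with_skbio_topology(self, rng):
        from skbio.tree import nj as skbio_nj
        n = 8
        raw = rng.uniform(0, 0.02, size=(n, n))
        noise = (raw + raw.T) / 2  # exactly symmetric perturbation
        true = _random_tree(rng, n)
        base = true.tip_tip_distances()
        data = base.data + noise
        np.fill_diagonal(data, 0.0)
        dm = DistanceMatrix(data, base.ids)
        ours = neighbor_joining(dm)
        theirs = skbio_nj(dm)
        assert ours.compare_rfd(theirs) == 0.0

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix([[0, 1], [1, 0]], ["a", "b"]))


def _brute_fitch(tree: TreeNode, alignment: dict[str, str]) -> int:
    """Independent oracle: minimise state changes by exhaustive enumeration
    of internal-node assignments, column by column."""
    t = tree.copy()
    internals = [n for n in t.traverse() if not n.is_tip()]
    edges = [(n, n.parent) for n in t.traverse() if n.parent is not None]
    ncols = len(next(iter(alignment.values())))
    wild = set(BASES)
    total = 0
    for col in range(ncols):
        states = {}
        for leaf in t.tips():
            c = alignment[leaf.name][col]
            states[id(leaf)] = {c} if c in wild else wild
        best = None
        for assign in itertools.product(BASES, repeat=len(internals)):
            cost = 0
            pick = dict(states)
            for node, a in zip(internals, assign):
                pick[id(node)] = {a}
            for child, parent in edges:
                if not (pick[id(child)] & pick[id(parent)]):
                    cost += 1
            best = cost if best is None else min(best, cost)
        total += best
    return total


class TestFitch:
    def test_identical_alignment_scores_zero(self):
        tree = parse_newick("((a,b),(c,d));")
        aln = {k: "ACGTACGT" for k in "abcd"}
        assert fitch_score(tree, aln) == 0

    def test_textbook_single_change(self):
        tree = parse_newick("((a,b),(c,d));")
        aln = {"a": "A", "b": "A", "c": "C", "d": "C"}
        assert fitch_score(tree, aln) == 1

    def test_gaps_are_wildcards(self):
        tree = parse_newick("((a,b),(c,d));")
        aln = {"a": "A", "b": "-", "c": "N", "d": "C"}
        assert fitch_score(tree, aln) == 1

    def test_matches_exhaustive_enumeration(self, rng):
        tree = parse_newick("((a,b),(c,(d,e)));")
        aln = {k: "".join(rng.choice(BASES + ["-"], size=10)) for k in "abcde"}
        assert fitch_score(tree, aln) == _brute_fitch(tree, aln)

    def test_missing_leaf_sequence_rejected(self):
        tree = parse_newick("((a,b),(c,d));")
        with pytest.raises(KeyError):
            fitch_score(tree, {"a": "A", "b": "A", "c": "C"})


class TestPlacement:
    def _ref_case(self, rng, n=6):
        root = _rand_seq(rng, 60)
        aln = {f"t{i}": _mut(root, 6, rng) for i in range(n)}
        tree = neighbor_joining(distance_matrix(aln, model="p"))
        return tree, aln

    def test_query_identical_to_leaf_lands_on_its_pendant_branch(self, rng):
        tree, aln = self._ref_case(rng)
        best, scored = parsimony_place("q", aln["t3"], tree, aln,
                                       already_aligned=True)
        best_name = next(nm for b, nm, s in scored if b == best)
        assert best_name == "t3"

    def test_two_leaf_tree_single_branch(self):
        tree = parse_newick("(a,b);")
        aln = {"a": "ACGT", "b": "ACGA"}
        best, scored = parsimony_place("q", "ACGT", tree, aln, already_aligned=True)
        assert len(scored) == 2  # one pendant branch per leaf
        assert best in {s[0] for s in scored}

    def test_best_branch_minimises_over_exhaustive_scores(self, rng):
        tree, aln = self._ref_case(rng, n=6)
        query = _mut(aln["t0"], 3, rng)
        best, scored = parsimony_place("q", query, tree, aln, already_aligned=True)
        best_score = next(s for b, _, s in scored if b == best)
        assert best_score == min(s for _, _, s in scored)
        # cross-check every branch score with the enumeration oracle
        nodes = [n for n in tree.preorder() if n is not tree]
        full = dict(aln, q=query)
        for bid, _, s in scored:
            t = tree.copy()
            target = [n for n in t.preorder() if n is not t][bid]
            parent = target.parent
            parent.remove(target)
            parent.append(TreeNode(children=[target, TreeNode(name="q")]))
            assert s == _brute_fitch(t, full)

    def test_profile_alignment_maps_query_onto_columns(self, rng):
        aln = {f"t{i}": _rand_seq(rng, 40) for i in range(4)}
        q = align_query_to_profile(aln["t0"], aln)
        assert len(q) == 40


class TestNewickIO:
    def test_round_trip(self, tmp_path):
        tree = parse_newick("(a:1,b:2,(c:3,d:4):5);")
        p = tmp_path / "t.nwk"
        write_newick(tree, p)
        back = read_newick(p)
        assert back.compare_rfd(tree) == 0.0
        assert {t.name: t.length for t in back.tips()} == {
            "a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0}

    def test_unlabeled_internal_nodes_accepted(self):
        tree = parse_newick("((a,b),(c,d));")
        assert len(list(tree.tips())) == 4

    def test_unbalanced_parenthesis_rejected(self):
        with pytest.raises(ValueError):
            parse_newick("((a,b),(c,d);")
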
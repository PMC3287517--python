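"""Desk-scale phylogenetics: nearest reference, neighbour joining, and
parsimony placement of query sequences into a reference tree.

The algorithms are the textbook ones — Saitou–Nei neighbour joining on a
p- or Jukes–Cantor-corrected distance matrix, Fitch small parsimony with
gaps/N as wildcards, and placement by exhaustively scoring the query on
every branch of the reference tree.  Exhaustive branch evaluation is
exact and entirely feasible for reference sets of tens of sequences,
which is the scale this package targets (a curated reference FASTA
rather than a full rRNA database).

Trees are :class:`skbio.TreeNode` objects throughout; distance matrices
are :class:`skbio.DistanceMatrix`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from io import StringIO

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .dna import encode
from .otu import pairwise_identity


@dataclass(frozen=True)
class ReferenceRecord:
    """One labelled reference sequence (accession, display label, optional
    clade/group, bases)."""

    accession: str
    label: str
    bases: str
    group: str | None = None

    def __post_init__(self) -> None:
        if not self.accession or not self.bases:
            raise ValueError("accession and bases must be non-empty")


def best_hit(query: str, refs: list[ReferenceRecord]) -> tuple[str, float]:
    """Reference with maximal pairwise identity to the query; ties broken
    by lexicographically smallest accession.  Returns (accession, identity)."""
    if not refs:
        raise ValueError("empty reference set")
    best = None
    for ref in sorted(refs, key=lambda r: r.accession):
        ident = pairwise_identity(query, ref.bases)
        if best is None or ident > best[1]:
            best = (ref.accession, ident)
    return best


def distance_matrix(alignment: dict[str, str], model: str = "jc69") -> DistanceMatrix:
    """Pairwise distances from an alignment (equal-length sequences).

    ``p``: pairwise-deletion p-distance — per pair, only columns where
    both sequences have a concrete A/C/G/T base are counted.
    ``jc69``: Jukes–Cantor correction ``-(3/4) ln(1 - 4p/3)``; a pair
    with p >= 0.75 is unresolvable under the model and raises.
    """
    if model not in ("p", "jc69"):
        raise ValueError(f"unknown model {model!r}")
    labels = list(alignment)
    if len(labels) < 3:
        raise ValueError("need at least 3 sequences")
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ValueError("sequences must be aligned to equal length")
    enc = {l: encode(alignment[l]) for l in labels}
    concrete = {l: np.isin(enc[l], (1, 2, 4, 8)) for l in labels}
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            li, lj = labels[i], labels[j]
            both = concrete[li] & concrete[lj]
            valid = int(both.sum())
            if valid == 0:
                raise ValueError(f"no comparable columns between {li!r} and {lj!r}")
            p = float((enc[li][both] != enc[lj][both]).sum()) / valid
            if model == "jc69":
                if p >= 0.75:
                    raise ValueError(
                        f"p-distance {p:.3f} between {li!r} and {lj!r} is "
                        "saturated under JC69"
                    )
                p = -0.75 * math.log1p(-4.0 * p / 3.0)
            d[i, j] = d[j, i] = p
    return DistanceMatrix(d, labels)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbour joining; returns an unrooted tree (root node
    of degree 3 for >= 4 taxa).

    Ties in the Q criterion are broken by the lexicographically smallest
    label pair.  A negative branch length is clamped to zero and its
    deficit moved to the sister branch, preserving the pair's summed
    length.
    """
    labels = list(dm.ids)
    if len(labels) < 3:
        raise ValueError("neighbour joining needs >= 3 taxa")
    d = {a: {b: float(dm[a, b]) for b in labels} for a in labels}
    nodes: dict[str, TreeNode] = {l: TreeNode(name=l) for l in labels}
    active = sorted(labels)
    counter = 0
    while len(active) > 3:
        n = len(active)
        r = {a: sum(d[a][b] for b in active if b != a) for a in active}
        best = None
        for ii, a in enumerate(active):
            for b in active[ii + 1:]:
                q = (n - 2) * d[a][b] - r[a] - r[b]
                key = (q, a, b)
                if best is None or key < best:
                    best = key
        _, a, b = best
        la = 0.5 * d[a][b] + (r[a] - r[b]) / (2 * (n - 2))
        lb = d[a][b] - la
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        la, lb = max(la, 0.0), max(lb, 0.0)
        counter += 1
        u = f"__nj{counter}"
        na, nb = nodes.pop(a), nodes.pop(b)
        na.length, nb.length = la, lb
        nodes[u] = TreeNode(children=[na, nb])
        d[u] = {}
        for c in active:
            if c in (a, b):
                continue
            duc = 0.5 * (d[a][c] + d[b][c] - d[a][b])
            d[u][c] = d[c][u] = max(duc, 0.0)
        active = sorted([c for c in active if c not in (a, b)] + [u])
    a, b, c = active
    la = 0.5 * (d[a][b] + d[a][c] - d[b][c])
    lb = 0.5 * (d[a][b] + d[b][c] - d[a][c])
    lc = 0.5 * (d[a][c] + d[b][c] - d[a][b])
    children = []
    for lbl, ln in ((a, la), (b, lb), (c, lc)):
        node = nodes.pop(lbl)
        node.length = max(ln, 0.0)
        children.append(node)
    return TreeNode(children=children)


def _rooted_binary(tree: TreeNode) -> TreeNode:
    """A strictly binary rooted copy of an unrooted tree (the parsimony
    score is invariant to the rooting)."""
    t = tree.copy()
    if len(t.children) <= 2:
        return t
    first = t.children[0]
    t.remove(first)
    return TreeNode(children=[first, t])


def fitch_score(tree: TreeNode, alignment: dict[str, str]) -> int:
    """Fitch small-parsimony changes summed over alignment columns.

    Gaps, N and ambiguity codes contribute their allowed-state set (gap
    and N act as wildcards and never force a change).
    """
    t = _rooted_binary(tree)
    for leaf in t.tips():
        if leaf.name not in alignment:
            raise KeyError(f"leaf {leaf.name!r} has no sequence")
    ncols = len(next(iter(alignment.values())))
    score = np.zeros(ncols, dtype=np.int64)

    def post(node: TreeNode) -> np.ndarray:
        if node.is_tip():
            enc = encode(alignment[node.name])
            return np.where(enc == 0, np.uint8(15), enc)  # gap/other -> wildcard
        masks = [post(ch) for ch in node.children]
        acc = masks[0]
        for m in masks[1:]:
            inter = acc & m
            empty = inter == 0
            score[empty] += 1
            acc = np.where(empty, acc | m, inter)
        return acc

    post(t)
    return int(score.sum())


def align_query_to_profile(query: str, ref_alignment: dict[str, str]) -> str:
    """Map a query onto the columns of a reference alignment.

    The query is globally aligned to the alignment's majority-rule
    consensus; query bases falling on consensus columns are kept,
    insertions relative to the consensus are dropped, and uncovered
    columns become gaps.
    """
    from .otu import _aligned_strings

    ncols = len(next(iter(ref_alignment.values())))
    cons = []
    seqs = list(ref_alignment.values())
    for j in range(ncols):
        counts: dict[str, int] = {}
        for s in seqs:
            if s[j] in "ACGT":
                counts[s[j]] = counts.get(s[j], 0) + 1
        cons.append(max(sorted(counts), key=lambda b: counts[b]) if counts else "A")
    ra, rq = _aligned_strings("".join(cons), query)
    out = []
    for ca, cq in zip(ra, rq):
        if ca == "-":
            continue  # insertion relative to the profile: dropped
        out.append(cq if cq in "ACGT" else "-")
    return "".join(out)


def parsimony_place(
    query_name: str,
    query: str,
    tree: TreeNode,
    ref_alignment: dict[str, str],
    already_aligned: bool = False,
) -> tuple[int, list[tuple[int, str, int]]]:
    """Place a query on the branch of ``tree`` minimising the Fitch score.

    Every branch is scored exhaustively; ties go to the branch first in a
    preorder traversal.  Returns ``(best_branch_id, scored)`` where
    ``scored`` lists ``(branch_id, child_node_name, score)`` for every
    branch (branch ids number the non-root nodes in preorder; each branch
    is the edge above that node).
    """
    aligned = query if already_aligned else align_query_to_profile(query, ref_alignment)
    full = dict(ref_alignment)
    full[query_name] = aligned
    nodes = [n for n in tree.preorder() if n is not tree]
    scored = []
    for bid, node in enumerate(nodes):
        t = tree.copy()
        target = [n for n in t.preorder() if n is not t][bid]
        parent = target.parent
        parent.remove(target)
        joint = TreeNode(children=[target, TreeNode(name=query_name)])
        parent.append(joint)
        scored.append((bid, node.name or f"internal_{bid}", fitch_score(t, full)))
    best = min(scored, key=lambda x: x[2])[0]
    return best, scored


def read_newick(path) -> TreeNode:
    """Read a Newick tree; malformed input raises ``ValueError``."""
    try:
        return TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises its own format error hierarchy
        raise ValueError(f"{path}: malformed Newick: {exc}") from exc


def parse_newick(text: str) -> TreeNode:
    try:
        return TreeNode.read(StringIO(text), format="newick")
    except Exception as exc:
        raise ValueError(f"malformed Newick: {exc}") from exc


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")
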
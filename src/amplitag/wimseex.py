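"""Window-match seed-extension consensus assembly of one tag pool.

The assembler is greedy and anchored: a seed is the longest read that
starts with the 24 bp anchor (the 4 bp library key plus the first 20 bp
of the forward primer) and is at least ``min_seed_size`` long.  The
contig then grows 3'-ward: each round, the contig's terminal
``window_size`` bases are searched in every available read; reads whose
match leaves an overhang past the contig end vote, column by column, on
up to one window's worth of new bases.  Extension is 3'-only because
seeds already start at the amplicon's 5' anchor.

After extension stops, the remaining pool reads that align within the
contig (by banded edit distance) are recruited as members, so a contig's
support counts every read it explains, not only the reads that happened
to extend its tip.  Membership is exclusive across contigs.  Finally the
contig is polished: member reads are piled up on the contig by alignment
and each column is replaced by its majority call, which removes the
residual errors frozen in from the seed read.

Assembly of a tag stops when no eligible seed remains or when the
cumulative length of extension-consumed reads reaches the ``max_bases``
budget (checked between seeds).
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import edlib
import numpy as np

from .dna import IUPAC, ambiguity_code, iupac_compatible, iupac_match, revcomp
from .seq_io import Read, SampleSheetRow

NO_MATCH = None

#: edlib equality extension: each IUPAC ambiguity code matches its
#: allowed concrete bases (so a canonicalised degenerate primer position
#: costs nothing against either variant).
EDLIB_EQUALITIES = [
    (code, base) for code, allowed in IUPAC.items() if len(allowed) > 1
    for base in allowed
]


@dataclass(frozen=True)
class WimseexParams:
    """Assembly parameters; defaults are the published run settings
    (200 bp minimum seed, 60 bp window, key + 20 bp of primer as anchor,
    500 kb per-tag base budget)."""

    min_seed_size: int = 200
    window_size: int = 60
    anchor_len_primer: int = 20
    max_bases: int = 500_000
    min_window_identity: float = 1.0
    min_support: int = 2
    polish_depth: int = 100

    def __post_init__(self) -> None:
        if self.min_seed_size < self.window_size:
            raise ValueError("min_seed_size must be >= window_size")
        if self.window_size < 8:
            raise ValueError("window_size must be >= 8")
        if self.max_bases <= self.min_seed_size:
            raise ValueError("max_bases must exceed min_seed_size")
        if not 0.0 < self.min_window_identity <= 1.0:
            raise ValueError("min_window_identity must be in (0, 1]")


@dataclass
class Contig:
    bases: str
    support: int
    members: list[str]
    sample: str = ""

    def __post_init__(self) -> None:
        if self.support != len(self.members) or self.support < 1:
            raise ValueError("support must equal len(members) >= 1")


def make_anchor(tag: SampleSheetRow, anchor_len_primer: int = 20) -> str:
    """Seed-detection anchor as an IUPAC pattern: the 4 bp key and the
    leading primer bases, with N wildcards over the 6 bp MID that sits
    between them on the read (the MID is already resolved upstream by
    demultiplexing, so seed detection does not re-check it)."""
    return tag.key + "N" * len(tag.mid_fwd) + tag.primer_fwd[:anchor_len_primer]


def detect_seeds(pool: list[Read], anchor: str, params: WimseexParams) -> list[Read]:
    """Reads long enough to seed whose prefix matches the anchor
    (IUPAC-aware), longest first, id as tie-break."""
    hits = [
        r for r in pool
        if len(r) >= params.min_seed_size
        and len(r) >= len(anchor)
        and iupac_match(anchor, r.bases[:len(anchor)])
    ]
    return sorted(hits, key=lambda r: (-len(r), r.id))


def window_match(contig_end: str, read: Read, params: WimseexParams):
    """Leftmost position in ``read`` where the contig's terminal window
    aligns at >= ``min_window_identity`` with at least one base of
    overhang beyond it; ``NO_MATCH`` otherwise.

    Matching is by banded edit distance (budget ``floor((1 -
    min_window_identity) * window_size)``), so a homopolymer indel inside
    the window — the platform's dominant error — still matches at
    identities below 1.  At identity 1.0 this is exact containment.
    """
    w = params.window_size
    if len(contig_end) != w:
        raise ValueError(f"contig_end must be exactly window_size={w} bp")
    hit = _find_window(contig_end, read.bases, params.min_window_identity)
    return NO_MATCH if hit is None else hit[0]


def _find_window(window: str, bases: str, min_identity: float):
    """(start, end_exclusive) of the leftmost best-scoring occurrence of
    ``window`` in ``bases`` that leaves at least one base of overhang."""
    w = len(window)
    k = int((1.0 - min_identity) * w)
    res = edlib.align(window, bases, mode="HW", task="locations", k=k,
                      additionalEqualities=EDLIB_EQUALITIES)
    if res["editDistance"] == -1:
        return None
    for start, end in res["locations"]:
        if end + 1 < len(bases):
            return (start if start is not None else 0, end + 1)
    return None


def _majority_base(counter: Counter) -> str:
    top = max(counter.values())
    tied = sorted(b for b, c in counter.items() if c == top)
    if len(tied) == 1:
        return tied[0]
    return ambiguity_code(set().union(*(set(b) for b in tied)) & set("ACGT")
                          or set(tied))


def extend(seed: Read, pool: list[Read], params: WimseexParams) -> Contig:
    """Grow a contig from a seed by repeated terminal-window matching.

    All reads of ``pool`` may vote each round (a member keeps voting in
    later rounds as the window slides across it); a read enters
    ``members`` the first round it matches.  Each round appends the
    column-wise majority of the matched reads' overhangs, at most one
    window length; ties become IUPAC codes.  The loop ends when no read
    overhangs the contig tip.
    """
    w = params.window_size
    contig = seed.bases
    members: list[str] = [seed.id]
    member_set = {seed.id}
    # hard cap: a contig can never legitimately outgrow its read pool, so a
    # repetitive terminal window cannot drive unbounded extension
    max_len = sum(len(r) for r in pool)
    while len(contig) < max_len:
        # When the terminal window finds no partner, erode: slide the window
        # back up to w/2 bases and let the majority overhang replace the
        # eroded tip.  Seeds are the longest reads and therefore enriched
        # for homopolymer insertions; a corrupt tip must not end assembly.
        overhangs: list[str] = []
        matched: list[Read] = []
        used_t = None
        for t in range(0, w // 2 + 1):
            if len(contig) < w + t:
                break
            window = contig[len(contig) - w - t: len(contig) - t]
            ov: list[str] = []
            mt: list[Read] = []
            for r in pool:
                hit = _find_window(window, r.bases, params.min_window_identity)
                if hit is None:
                    continue
                tail = r.bases[hit[1]:]
                if tail:
                    ov.append(tail)
                    mt.append(r)
            if ov and max(len(o) for o in ov) > t:
                overhangs, matched, used_t = ov, mt, t
                break
        if used_t is None:
            break
        for r in matched:
            if r.id not in member_set:
                member_set.add(r.id)
                members.append(r.id)
        ext_len = min(w, max(len(o) for o in overhangs))
        cols = []
        for j in range(ext_len):
            votes = Counter(o[j] for o in overhangs if len(o) > j)
            cols.append(_majority_base(votes))
        if used_t:
            contig = contig[: len(contig) - used_t]
        contig += "".join(cols)
    return Contig(bases=contig, support=len(members), members=members)


def _recruit(contig: str, pool: list[Read], claimed: set[str],
             params: WimseexParams) -> list[Read]:
    """Reads contained in the contig within the identity budget
    implied by ``min_window_identity`` (edit distance, infix mode)."""
    out = []
    for r in pool:
        if r.id in claimed:
            continue
        k = int((1.0 - params.min_window_identity) * len(r.bases))
        res = edlib.align(r.bases, contig, mode="HW", task="distance", k=k,
                          additionalEqualities=EDLIB_EQUALITIES)
        if res["editDistance"] != -1:
            out.append(r)
    return out


def _polish(contig: str, members: list[Read], params: WimseexParams) -> str:
    """Majority-polish a contig from a pileup of member alignments.

    Uses at most ``polish_depth`` members (longest first — ample coverage
    for a majority call).  Substitution and deletion votes are applied
    per contig column; ties keep the existing contig base, so a
    zero-noise contig passes through unchanged.  Insertions relative to
    the contig are applied after a column when a strict majority of the
    reads covering that column supports the same inserted string.
    """
    subset = sorted(members, key=lambda r: (-len(r), r.id))[:params.polish_depth]
    col_votes: dict[int, Counter] = defaultdict(Counter)
    ins_votes: dict[int, Counter] = defaultdict(Counter)
    coverage = np.zeros(len(contig), dtype=int)
    cig_re = re.compile(r"(\d+)([=XIDM])")
    for r in subset:
        res = edlib.align(r.bases, contig, mode="HW", task="path",
                          additionalEqualities=EDLIB_EQUALITIES)
        if res["editDistance"] == -1:
            continue
        start = res["locations"][0][0]
        ci, ri = start, 0
        for n_str, op in cig_re.findall(res["cigar"]):
            n = int(n_str)
            if op in "=XM":
                for t in range(n):
                    col_votes[ci + t][r.bases[ri + t]] += 1
                coverage[ci:ci + n] += 1
                ci += n
                ri += n
            elif op == "D":  # read skips contig bases -> deletion votes
                for t in range(n):
                    col_votes[ci + t]["-"] += 1
                coverage[ci:ci + n] += 1
                ci += n
            elif op == "I":  # read has extra bases after contig column ci-1
                ins_votes[ci - 1][r.bases[ri:ri + n]] += 1
                ri += n
    out = []
    for i, base in enumerate(contig):
        votes = col_votes.get(i)
        call = base
        if votes:
            top = max(votes.values())
            tied = sorted(b for b, c in votes.items() if c == top)
            if base not in tied:
                call = tied[0] if len(tied) == 1 else _majority_base(votes)
        if call != "-":
            out.append(call)
        if i in ins_votes:
            ins, n_ins = ins_votes[i].most_common(1)[0]
            if coverage[i] > 0 and n_ins > coverage[i] / 2:
                out.append(ins)
    return "".join(out)


def _canonicalize(contig: str, tag: SampleSheetRow) -> str:
    """Rewrite the known amplicon framing back onto a contig.

    When the contig's 5' end is compatible with ``key + mid_fwd +
    primer_fwd`` (or its 3' end with the reverse-complemented reverse
    block), those positions are replaced by the pattern itself, restoring
    IUPAC codes at degenerate primer positions.  Reads carrying either
    concrete variant then align to the contig at zero cost, so support is
    not split across primer-pool variants.
    """
    prefix = tag.key + tag.mid_fwd + tag.primer_fwd
    if len(contig) >= len(prefix) and iupac_compatible(prefix, contig[:len(prefix)]):
        contig = prefix + contig[len(prefix):]
    tail = revcomp(tag.key + tag.mid_rev + tag.primer_rev)
    if len(contig) >= len(prefix) + len(tail) and iupac_compatible(tail, contig[-len(tail):]):
        contig = contig[:-len(tail)] + tail
    return contig


def assemble_tag(pool: list[Read], anchor: str, params: WimseexParams,
                 sample: str = "", tag: SampleSheetRow | None = None) -> list[Contig]:
    """Assemble one demultiplexed tag pool into consensus contigs.

    Seeds are processed greedily; each contig claims its members
    exclusively; the base budget counts extension-consumed reads and is
    checked between seeds.  Contigs with support below ``min_support``
    are discarded; the rest are returned by support, descending.
    """
    claimed: set[str] = set()
    contigs: list[Contig] = []
    consumed_bases = 0
    while consumed_bases < params.max_bases:
        available = [r for r in pool if r.id not in claimed]
        seeds = detect_seeds(available, anchor, params)
        if not seeds:
            break
        seed = seeds[0]
        contig = extend(seed, available, params)
        consumed_bases += sum(len(r) for r in available if r.id in set(contig.members))
        claimed.update(contig.members)
        by_id = {r.id: r for r in available}

        def _clean(bases: str, member_ids: list[str]) -> str:
            bases = _polish(bases, [by_id[i] for i in member_ids], params)
            return _canonicalize(bases, tag) if tag is not None else bases

        # polish on the extension members first: recruitment needs a
        # low-error consensus or honest reads overrun the edit budget
        contig.bases = _clean(contig.bases, contig.members)
        recruited = _recruit(contig.bases, available, claimed, params)
        contig.members.extend(r.id for r in recruited)
        contig.support = len(contig.members)
        claimed.update(r.id for r in recruited)
        contig.bases = _clean(contig.bases, contig.members)
        contig.sample = sample
        contigs.append(contig)
    contigs = [c for c in contigs if c.support >= params.min_support]
    return sorted(contigs, key=lambda c: (-c.support, c.bases))
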
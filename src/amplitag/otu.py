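"""From contigs to consensus OTUs and a per-sample abundance table.

Contigs from one sample are clustered greedily around the
highest-support centroids at a configurable identity radius (default
0.97, the conventional species-level 16S cutoff), each cluster is
collapsed to a support-weighted consensus, the key/MID/primer framing is
stripped, and read counts are tabulated per sample with percentages of
the sample total — the shape of a classic amplicon survey table.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd
from Bio import Align

from .dna import ambiguity_code, iupac_compatible, iupac_match, revcomp
from .seq_io import SampleSheetRow
from .wimseex import Contig

DEFAULT_IDENTITY = 0.97


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner(mode="global")
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -2
    a.extend_gap_score = -0.5
    return a


_ALIGNER = _aligner()


def _aligned_strings(a: str, b: str) -> tuple[str, str]:
    aln = _ALIGNER.align(a, b)[0]
    return str(aln[0]), str(aln[1])


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity: matching columns / alignment columns,
    terminal gap columns excluded.

    Scoring: match +1, mismatch -1, gap open -2, gap extend -0.5.
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    ra, rb = _aligned_strings(a, b)
    # trim columns where either sequence has not started / has ended
    start = max(len(ra) - len(ra.lstrip("-")), len(rb) - len(rb.lstrip("-")))
    end = len(ra) - max(len(ra) - len(ra.rstrip("-")), len(rb) - len(rb.rstrip("-")))
    cols = end - start
    if cols <= 0:
        raise ValueError("alignment has no internal columns")
    matches = sum(ra[i] == rb[i] and ra[i] != "-" for i in range(start, end))
    return matches / cols


def cluster(contigs: list[Contig], identity_threshold: float = DEFAULT_IDENTITY
            ) -> list[list[Contig]]:
    """Greedy centroid clustering of one sample's contigs.

    Contigs are taken by support descending (sequence as tie-break); each
    joins the first existing centroid within the identity radius, else
    founds a new cluster.  Deterministic; the centroid is each cluster's
    first element.
    """
    clusters: list[list[Contig]] = []
    for c in sorted(contigs, key=lambda c: (-c.support, c.bases)):
        for cl in clusters:
            if pairwise_identity(c.bases, cl[0].bases) >= identity_threshold:
                cl.append(c)
                break
        else:
            clusters.append([c])
    return clusters


def consensus_of_cluster(members: list[Contig]) -> str:
    """Support-weighted consensus of a cluster, anchored on its centroid.

    Each non-centroid member is pairwise-aligned to the centroid; votes
    are collected per centroid column (substitutions and deletions) and
    per insertion point.  The majority symbol wins each column, weighted
    by contig support; ties between bases become IUPAC codes; a gap/base
    tie keeps the base; all-gap columns are dropped.  Insertions are
    emitted when their supporting weight exceeds half the cluster weight.
    """
    if not members:
        raise ValueError("empty cluster")
    centroid = members[0]
    n = len(centroid.bases)
    col_votes: list[dict[str, int]] = [dict() for _ in range(n)]
    ins_votes: list[dict[str, int]] = [dict() for _ in range(n + 1)]
    total_weight = sum(m.support for m in members)

    def vote(d: dict[str, int], sym: str, w: int) -> None:
        d[sym] = d.get(sym, 0) + w

    for i, base in enumerate(centroid.bases):
        vote(col_votes[i], base, centroid.support)
    for m in members[1:]:
        ra, rb = _aligned_strings(centroid.bases, m.bases)
        ci = 0
        pending_ins: list[str] = []
        for ca, cb in zip(ra, rb):
            if ca == "-":
                pending_ins.append(cb)
                continue
            if pending_ins:
                vote(ins_votes[ci], "".join(pending_ins), m.support)
                pending_ins = []
            vote(col_votes[ci], cb, m.support)
            ci += 1
        if pending_ins:
            vote(ins_votes[ci], "".join(pending_ins), m.support)

    out: list[str] = []
    for i in range(n + 1):
        if ins_votes[i]:
            ins, w = max(ins_votes[i].items(), key=lambda kv: (kv[1], kv[0]))
            if w > total_weight / 2:
                out.append(ins)
        if i == n:
            break
        votes = col_votes[i]
        top = max(votes.values())
        tied = sorted(s for s, w in votes.items() if w == top)
        bases = [t for t in tied if t != "-"]
        if not bases:
            continue  # gap wins outright: column dropped
        if len(bases) == 1:
            out.append(bases[0])
        else:
            out.append(ambiguity_code(set("".join(bases)) & set("ACGT") or bases))
    return "".join(out)


def strip_tag_primer(seq: str, tag: SampleSheetRow, strip_suffix: bool = True
                     ) -> tuple[str, bool]:
    """Remove the key+MID+primer framing from a consensus sequence.

    Strips the leading ``key + mid_fwd + primer_fwd`` block when present
    (primer matched IUPAC-aware) and, when ``strip_suffix`` is set, the
    trailing ``revcomp(key + mid_rev + primer_rev)`` block.  Returns
    ``(sequence, warning)`` with ``warning=True`` when the leading block
    was absent and the sequence is returned as-is on that end.
    """
    prefix_pat = tag.key + tag.mid_fwd + tag.primer_fwd
    p = len(prefix_pat)
    warning = True
    if len(seq) > p and iupac_compatible(prefix_pat, seq[:p]):
        seq = seq[p:]
        warning = False
    if strip_suffix:
        suffix_pat = revcomp(tag.key + tag.mid_rev + tag.primer_rev)
        s = len(suffix_pat)
        if len(seq) > s and iupac_compatible(suffix_pat, seq[-s:]):
            seq = seq[:-s]
    return seq, warning


@dataclass
class ConsensusOTU:
    """One consensus OTU: stripped sequence plus its read support."""

    otu_id: str
    bases: str
    sample: str
    read_count: int
    closest_match: str | None = None

    def __post_init__(self) -> None:
        if self.read_count < 1:
            raise ValueError("read_count must be >= 1")


def contigs_to_otus(contigs: list[Contig], tag: SampleSheetRow,
                    identity_threshold: float = DEFAULT_IDENTITY) -> list[ConsensusOTU]:
    """Cluster one sample's contigs, build consensus sequences, strip the
    tag/primer framing and attach summed read support."""
    otus = []
    for k, cl in enumerate(cluster(contigs, identity_threshold), start=1):
        cons = consensus_of_cluster(cl)
        stripped, _ = strip_tag_primer(cons, tag)
        otus.append(
            ConsensusOTU(
                otu_id=f"{tag.sample}_OTU{k:02d}",
                bases=stripped,
                sample=tag.sample,
                read_count=sum(c.support for c in cl),
            )
        )
    return sorted(otus, key=lambda o: -o.read_count)


TABLE_COLUMNS = ["sample", "otu_id", "read_count", "pct_of_total", "closest_match"]


def build_table(otus_by_sample: dict[str, list[ConsensusOTU]]) -> pd.DataFrame:
    """Per-sample abundance table: read counts and percentages of the
    sample total (2 decimals), rows sorted by count descending."""
    rows = []
    for sample, otus in otus_by_sample.items():
        total = sum(o.read_count for o in otus)
        if total == 0:
            raise ValueError(f"sample {sample!r} has zero reads")
        for o in sorted(otus, key=lambda o: (-o.read_count, o.otu_id)):
            rows.append(
                (sample, o.otu_id, o.read_count,
                 round(100.0 * o.read_count / total, 2), o.closest_match)
            )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def dominant_fraction(table: pd.DataFrame, otu_subset, samples=None) -> float:
    """Percentage of all reads (optionally restricted to ``samples``)
    carried by the OTUs in ``otu_subset``."""
    if table.empty:
        raise ValueError("empty table")
    t = table if samples is None else table[table["sample"].isin(list(samples))]
    total = t["read_count"].sum()
    if total == 0:
        raise ValueError("no reads in selection")
    subset = t[t["otu_id"].isin(set(otu_subset))]["read_count"].sum()
    return 100.0 * float(subset) / float(total)


def load_example_survey() -> pd.DataFrame:
    """Bundled example abundance survey: per-OTU read counts of
    endosymbiont 16S amplicons in larvae of four *Otiorhynchus* weevil
    species (black vine weevil and relatives), with each OTU's closest
    database match.  Columns: sample, otu_id, read_count, closest_match,
    taxon_class."""
    with resources.files("amplitag.data").joinpath("weevil_survey_counts.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
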
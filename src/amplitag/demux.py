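"""Sample assignment by exact key + MID matching.

A read is assigned only when its first four bases equal the library key,
the following six bases equal one sample's forward or reverse MID with
zero mismatches, and the expected primer follows (IUPAC-aware, zero
mismatches by default).  Everything else is kept as data: unmatched reads
go to an UNASSIGNED pool, quality failures to QC_FAIL — assignment is a
partition, never a filter that silently drops reads.

Reverse-orientation reads are reverse-complemented into the forward frame
of the template before pooling, so each per-sample pool presents one
coordinate system to the assembler.  Such forward-framed former reverse
reads carry their key/MID/primer block reverse-complemented at their 3'
end; :func:`assign` recognises that layout too, which makes
demultiplexing idempotent on its own output pools.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .dna import iupac_mismatches, revcomp
from .seq_io import Read, SampleSheetRow

UNASSIGNED = "UNASSIGNED"
QC_FAIL = "QC_FAIL"

# re-export: the primitive lives in dna but is part of this module's surface
from .dna import iupac_match  # noqa: E402,F401


@dataclass
class DemuxResult:
    """Assignment outcome for one read.

    Spans are 0-based half-open intervals on the read as given.  For a
    prefix-anchored read they are contiguous and ordered key < mid <
    primer with ``insert_start == primer_span[1]``; for a read already in
    forward frame (tag block at the 3' end) the spans sit at the tail and
    ``insert_start`` is 0.
    """

    read: Read
    sample: str
    orientation: str  # "fwd" | "rev" | "NA"
    key_span: tuple[int, int] | None = None
    mid_span: tuple[int, int] | None = None
    primer_span: tuple[int, int] | None = None
    insert_start: int | None = None


def quality_filter(read: Read, min_mean_q: float = 20.0, max_n: int = 0) -> bool:
    """True iff mean quality >= ``min_mean_q`` (vacuously true without
    qualities) and the count of N bases is <= ``max_n``."""
    if read.bases.count("N") > max_n:
        return False
    if read.quals is None:
        return True
    return sum(read.quals) / len(read.quals) >= min_mean_q


def _try_prefix(read: Read, row: SampleSheetRow, orientation: str,
                primer_mismatches: int) -> DemuxResult | None:
    mid = row.mid_fwd if orientation == "fwd" else row.mid_rev
    primer = row.primer_fwd if orientation == "fwd" else row.primer_rev
    k, m, p = len(row.key), len(mid), len(primer)
    if len(read.bases) < k + m + p:
        return None
    if read.bases[:k] != row.key or read.bases[k:k + m] != mid:
        return None
    if iupac_mismatches(primer, read.bases[k + m:k + m + p]) > primer_mismatches:
        return None
    return DemuxResult(
        read=read, sample=row.sample, orientation=orientation,
        key_span=(0, k), mid_span=(k, k + m), primer_span=(k + m, k + m + p),
        insert_start=k + m + p,
    )


def _try_fwd_frame_tail(read: Read, row: SampleSheetRow,
                        primer_mismatches: int) -> DemuxResult | None:
    # A former reverse read already flipped into forward frame ends with
    # revcomp(key + mid_rev + primer_rev).
    tail = revcomp(row.key + row.mid_rev + row.primer_rev)
    t = len(tail)
    if len(read.bases) < t:
        return None
    if iupac_mismatches(tail, read.bases[-t:]) > primer_mismatches:
        return None
    n = len(read.bases)
    k, m, p = len(row.key), len(row.mid_rev), len(row.primer_rev)
    return DemuxResult(
        read=read, sample=row.sample, orientation="fwd",
        key_span=(n - k, n), mid_span=(n - k - m, n - k),
        primer_span=(n - k - m - p, n - k - m), insert_start=0,
    )


def assign(read: Read, sheet: Sequence[SampleSheetRow],
           primer_mismatches: int = 0) -> DemuxResult:
    """Assign one read to a sample by exact key/MID match.

    Checks, in order: forward prefix anchor, reverse prefix anchor, then
    the forward-frame tail anchor left by :func:`demultiplex`'s
    orientation flip.  Sheet-level MID uniqueness guarantees at most one
    row can match, so no tie-breaking is ever needed.
    """
    for row in sheet:
        hit = _try_prefix(read, row, "fwd", primer_mismatches)
        if hit:
            return hit
        hit = _try_prefix(read, row, "rev", primer_mismatches)
        if hit:
            return hit
    for row in sheet:
        hit = _try_fwd_frame_tail(read, row, primer_mismatches)
        if hit:
            return hit
    return DemuxResult(read=read, sample=UNASSIGNED, orientation="NA")


@dataclass
class DemuxPools:
    """Partition of an input read set over samples plus UNASSIGNED / QC_FAIL."""

    pools: dict[str, list[Read]]
    summary: pd.DataFrame
    assignments: list[DemuxResult]

    def pool(self, name: str) -> list[Read]:
        return self.pools.get(name, [])


def demultiplex(
    reads: Iterable[Read],
    sheet: Sequence[SampleSheetRow],
    min_mean_q: float = 20.0,
    max_n: int = 0,
    primer_mismatches: int = 0,
) -> DemuxPools:
    """Partition reads into per-sample pools (forward frame) plus
    UNASSIGNED and QC_FAIL.  Every input read lands in exactly one pool."""
    pools: dict[str, list[Read]] = {row.sample: [] for row in sheet}
    pools[UNASSIGNED] = []
    pools[QC_FAIL] = []
    assignments: list[DemuxResult] = []
    total = 0
    for read in reads:
        total += 1
        if not quality_filter(read, min_mean_q, max_n):
            pools[QC_FAIL].append(read)
            assignments.append(DemuxResult(read=read, sample=QC_FAIL, orientation="NA"))
            continue
        res = assign(read, sheet, primer_mismatches)
        assignments.append(res)
        if res.sample == UNASSIGNED:
            pools[UNASSIGNED].append(read)
        elif res.orientation == "rev":
            flipped = Read(read.id, revcomp(read.bases),
                           None if read.quals is None else read.quals[::-1])
            pools[res.sample].append(flipped)
        else:
            pools[res.sample].append(read)
    summary = pd.DataFrame(
        [(name, len(pool)) for name, pool in pools.items()],
        columns=["category", "n_reads"],
    )
    assert int(summary["n_reads"].sum()) == total
    return DemuxPools(pools=pools, summary=summary, assignments=assignments)
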
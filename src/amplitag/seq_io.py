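"""Readers and writers for the external formats the pipeline touches.

FASTA / FASTQ parsing is delegated to Biopython; this module adds the
package's normalisation contract (uppercase, U->T, IUPAC-only alphabet,
Phred+33 qualities) and located parse errors.  Sample sheets are TSV with
the fixed header ``sample key mid_fwd mid_rev primer_fwd primer_rev``.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
from Bio import SeqIO

from .dna import normalize

SAMPLE_SHEET_COLUMNS = ["sample", "key", "mid_fwd", "mid_rev", "primer_fwd", "primer_rev"]


class ParseError(ValueError):
    """Malformed input file; the message names the file and location."""


@dataclass
class Read:
    """One sequencing read: identifier, bases, optional Phred qualities."""

    id: str
    bases: str
    quals: list[int] | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("read id must be non-empty")
        if not self.bases:
            raise ValueError(f"read {self.id!r}: empty sequence")
        if self.quals is not None and len(self.quals) != len(self.bases):
            raise ValueError(
                f"read {self.id!r}: {len(self.quals)} quality values for "
                f"{len(self.bases)} bases"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class SampleSheetRow:
    """Per-sample barcode bundle: 454 key, forward/reverse MID, primer pair."""

    sample: str
    key: str
    mid_fwd: str
    mid_rev: str
    primer_fwd: str
    primer_rev: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "key", normalize(self.key))
        object.__setattr__(self, "mid_fwd", normalize(self.mid_fwd))
        object.__setattr__(self, "mid_rev", normalize(self.mid_rev))
        object.__setattr__(self, "primer_fwd", normalize(self.primer_fwd))
        object.__setattr__(self, "primer_rev", normalize(self.primer_rev))
        if len(self.key) != 4:
            raise ValueError(f"sample {self.sample!r}: key must be 4 bp")
        if len(self.mid_fwd) != 6 or len(self.mid_rev) != 6:
            raise ValueError(f"sample {self.sample!r}: MIDs must be 6 bp")
        if not self.primer_fwd or not self.primer_rev:
            raise ValueError(f"sample {self.sample!r}: primers must be non-empty")


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path) -> Iterator[Read]:
    """Yield reads from a 4-line-record FASTQ file (Phred+33).

    Raises :class:`ParseError` naming the approximate line of a malformed
    record (records are 4 lines each).
    """
    seen: set[str] = set()
    n = 0
    with _open_text(path) as fh:
        parser = SeqIO.parse(fh, "fastq")
        while True:
            try:
                rec = next(parser)
            except StopIteration:
                break
            except ValueError as exc:
                raise ParseError(
                    f"{path}: malformed FASTQ record near line {4 * n + 1}: {exc}"
                ) from exc
            if rec.id in seen:
                raise ParseError(f"{path}: duplicate read id {rec.id!r}")
            seen.add(rec.id)
            n += 1
            yield Read(
                id=rec.id,
                bases=normalize(str(rec.seq)),
                quals=list(rec.letter_annotations["phred_quality"]),
            )


def read_fasta(path) -> Iterator[Read]:
    """Yield reads (without qualities) from a FASTA file, in file order."""
    seen: set[str] = set()
    with _open_text(path) as fh:
        first = True
        for line in fh:
            if line.strip():
                if first and not line.startswith(">"):
                    raise ParseError(f"{path}: sequence data before first '>' header")
                break
        fh.seek(0)
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise ParseError(f"{path}: duplicate record id {rec.id!r}")
            seen.add(rec.id)
            yield Read(id=rec.id, bases=normalize(str(rec.seq)))


def write_fasta(records: Iterable[Read], path) -> None:
    with _open_text(path, "wt") as fh:
        for r in records:
            fh.write(f">{r.id}\n{r.bases}\n")


def write_fastq(records: Iterable[Read], path) -> None:
    with _open_text(path, "wt") as fh:
        for r in records:
            if r.quals is None:
                raise ValueError(f"read {r.id!r} has no qualities; cannot write FASTQ")
            qline = "".join(chr(q + 33) for q in r.quals)
            fh.write(f"@{r.id}\n{r.bases}\n+\n{qline}\n")


def read_sample_sheet(path) -> list[SampleSheetRow]:
    """Load and validate a TSV sample sheet.

    MIDs must be unique across all rows and both orientations (a MID seen
    twice would make assignment ambiguous).  Note the reverse MID of a
    sample is typically the reverse complement of its forward MID; that is
    allowed — only literal string duplication is rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != SAMPLE_SHEET_COLUMNS:
        raise ParseError(
            f"{path}: sample sheet header must be {SAMPLE_SHEET_COLUMNS}, "
            f"got {list(df.columns)}"
        )
    rows = []
    for i, rec in enumerate(df.itertuples(index=False)):
        try:
            rows.append(SampleSheetRow(*rec))
        except ValueError as exc:
            raise ParseError(f"{path}: row {i + 2}: {exc}") from exc
    names = [r.sample for r in rows]
    if len(set(names)) != len(names):
        raise ParseError(f"{path}: duplicate sample names")
    mids = [m for r in rows for m in (r.mid_fwd, r.mid_rev)]
    dupes = {m for m in mids if mids.count(m) > 1}
    if dupes:
        raise ParseError(f"{path}: MID used more than once: {sorted(dupes)}")
    return rows


def write_sample_sheet(rows: Sequence[SampleSheetRow], path) -> None:
    pd.DataFrame([vars(r) if not hasattr(r, "__dataclass_fields__") else
                  {c: getattr(r, c) for c in SAMPLE_SHEET_COLUMNS} for r in rows]).to_csv(
        path, sep="\t", index=False)
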
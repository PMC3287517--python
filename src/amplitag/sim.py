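"""454-style multitag amplicon read simulation with known ground truth.

The simulator emulates what a GS FLX Titanium run sees after library
construction: each amplicon is framed as ``key + MID + primer + insert``
(the Titanium A/B adaptors are stripped by the instrument before the key
and are not emitted).  Reads from the B end carry the reverse MID/primer
and the reverse-complemented insert.  The error model is dominated by
homopolymer-length indels, the platform's characteristic failure mode,
plus a small uniform substitution rate.

Every random decision flows from a single integer seed, so identical
inputs reproduce byte-identical read sets and truth tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import groupby

import numpy as np
import pandas as pd

from .dna import normalize, resolve_iupac, revcomp
from .seq_io import Read, SampleSheetRow

#: Phred quality assigned to every simulated base.  The model does not
#: simulate per-base quality decay; a single high value keeps simulated
#: reads above any sensible mean-quality filter.
SIM_QUALITY = 35


@dataclass(frozen=True)
class ErrorModel:
    """Per-read noise and length model for simulated 454 reads.

    sub_rate
        Per-base substitution probability (uniform over the 3 alternatives).
    hp_indel_base, hp_scale
        A maximal homopolymer run of length ``k`` gains or loses one base
        with probability ``min(0.5, hp_indel_base * hp_scale**(k-1))``;
        insertion and deletion are equiprobable.
    len_mean, len_sd
        Insert (template portion) length in bp, drawn Normal and clamped
        to [100, template length].
    rev_read_frac
        Fraction of reads sequenced from the reverse (B-adaptor) end.
    """

    sub_rate: float = 0.004
    hp_indel_base: float = 0.01
    hp_scale: float = 1.6
    len_mean: float = 430.0
    len_sd: float = 25.0
    rev_read_frac: float = 0.5

    def __post_init__(self) -> None:
        for p in (self.sub_rate, self.hp_indel_base, self.rev_read_frac):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.len_mean <= 0:
            raise ValueError("len_mean must be positive")

    def hp_indel_prob(self, run_length: int) -> float:
        return min(0.5, self.hp_indel_base * self.hp_scale ** (run_length - 1))


ZERO_NOISE = ErrorModel(sub_rate=0.0, hp_indel_base=0.0)


@dataclass
class CommunityProfile:
    """Ground-truth composition of one tagged sample pool."""

    sample: str
    members: list[tuple[str, float]]  # (template_id, relative abundance)
    n_reads: int
    tag: SampleSheetRow

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise ValueError(f"profile {self.sample!r}: n_reads must be >= 1")
        total = sum(a for _, a in self.members)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"profile {self.sample!r}: abundances sum to {total}, not 1"
            )
        if any(a < 0 for _, a in self.members):
            raise ValueError(f"profile {self.sample!r}: negative abundance")


def build_amplicon(
    template: str,
    tag: SampleSheetRow,
    orientation: str,
    rng: np.random.Generator | None = None,
) -> str:
    """Frame a template insert as one sequencer-visible amplicon strand.

    fwd: ``key + mid_fwd + primer_fwd + template``;
    rev: ``key + mid_rev + primer_rev + revcomp(template)``.
    Degenerate primer positions are resolved per call (see
    :func:`amplitag.dna.resolve_iupac`).
    """
    if not template:
        raise ValueError("empty template")
    template = normalize(template)
    if orientation == "fwd":
        return tag.key + tag.mid_fwd + resolve_iupac(tag.primer_fwd, rng) + template
    if orientation == "rev":
        return tag.key + tag.mid_rev + resolve_iupac(tag.primer_rev, rng) + revcomp(template)
    raise ValueError(f"unknown orientation {orientation!r}")


def full_amplicon(template: str, tag: SampleSheetRow) -> str:
    """The complete double-tagged amplicon on the forward strand:
    ``key + mid_fwd + primer_fwd + template + revcomp(key + mid_rev + primer_rev)``.

    Degenerate primer positions are left as IUPAC codes; compare against
    assembled contigs with :func:`amplitag.dna.iupac_match`.
    """
    left = tag.key + tag.mid_fwd + tag.primer_fwd
    right = revcomp(tag.key + tag.mid_rev + tag.primer_rev)
    return left + normalize(template) + right


def mutate(seq: str, model: ErrorModel, rng_seed) -> str:
    """Apply the error model to one sequence, deterministically per seed.

    Substitutions are drawn first; homopolymer indels are then drawn per
    maximal run of the substituted sequence.  ``rng_seed`` may be an int
    or a ``numpy.random.Generator``.
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    bases = list(seq)
    if model.sub_rate > 0:
        hits = np.flatnonzero(rng.random(len(bases)) < model.sub_rate)
        for i in hits:
            alts = [b for b in "ACGT" if b != bases[i]]
            bases[i] = alts[int(rng.integers(3))]
    s = "".join(bases)
    if model.hp_indel_base == 0:
        return s
    out = []
    for base, run in groupby(s):
        k = len(list(run))
        if rng.random() < model.hp_indel_prob(k):
            k += 1 if rng.random() < 0.5 else -1
        out.append(base * k)
    return "".join(out)


def simulate(
    profiles: list[CommunityProfile],
    templates: dict[str, str],
    model: ErrorModel,
    rng_seed: int,
) -> tuple[list[Read], pd.DataFrame]:
    """Simulate tagged read pools for a set of community profiles.

    Returns the shuffled read list (as if one pooled sequencing run) and a
    truth table with one row per read: ``read_id, sample, template_id,
    orientation``.
    """
    if sum(p.n_reads for p in profiles) == 0:
        raise ValueError("no reads requested")
    rng = np.random.default_rng(rng_seed)
    reads: list[Read] = []
    truth_rows = []
    for profile in profiles:
        ids = [tid for tid, _ in profile.members]
        for tid in ids:
            if tid not in templates:
                raise KeyError(f"template {tid!r} not in template set")
        probs = np.array([a for _, a in profile.members], dtype=float)
        probs = probs / probs.sum()
        choices = rng.choice(len(ids), size=profile.n_reads, p=probs)
        for i, c in enumerate(choices):
            tid = ids[int(c)]
            template = templates[tid]
            length = int(round(rng.normal(model.len_mean, model.len_sd)))
            length = max(100, min(len(template), length))
            orientation = "rev" if rng.random() < model.rev_read_frac else "fwd"
            insert = template[:length] if orientation == "fwd" else template[-length:]
            amplicon = build_amplicon(insert, profile.tag, orientation, rng)
            bases = mutate(amplicon, model, rng)
            read_id = f"{profile.sample}_{i:06d}"
            reads.append(Read(read_id, bases, [SIM_QUALITY] * len(bases)))
            truth_rows.append((read_id, profile.sample, tid, orientation))
    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    truth = pd.DataFrame(
        [truth_rows[i] for i in order],
        columns=["read_id", "sample", "template_id", "orientation"],
    )
    return reads, truth


# ---------------------------------------------------------------------------
# Synthetic reference sequences
# ---------------------------------------------------------------------------

#: Clade layout of the synthetic reference set: (group, n members).
_SYN_CLADES = [
    ("Rickettsia-like", 4),
    ("Nardonella-like", 4),
    ("Neoehrlichia-like", 3),
    ("environmental", 2),
]


def synthetic_references(seed: int = 20120118) -> list[dict]:
    """A small synthetic stand-in for a 16S reference database.

    Generates ~450 bp sequences in three endosymbiont-like clades
    (Rickettsia-like, Nardonella/Blochmannia-like, Neoehrlichia-like) plus
    two environmental outliers.  Clades diverge ~15% from a common
    ancestor and ~2% within a clade.  These sequences are synthetic: they
    share no homology with any real 16S sequence and exist so the
    pipeline is testable without a database download.

    Returns a list of dicts with keys ``accession``, ``label``, ``group``,
    ``bases``, deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    length = 450

    def _random_seq(n):
        return "".join(rng.choice(list("ACGT"), size=n, p=[0.27, 0.23, 0.27, 0.23]))

    def _diverge(seq, rate):
        out = list(seq)
        hits = np.flatnonzero(rng.random(len(out)) < rate)
        for i in hits:
            alts = [b for b in "ACGT" if b != out[i]]
            out[i] = alts[int(rng.integers(3))]
        return "".join(out)

    ancestor = _random_seq(length)
    records = []
    idx = 1
    for group, n in _SYN_CLADES:
        clade_anc = _diverge(ancestor, 0.15)
        for j in range(n):
            bases = _diverge(clade_anc, 0.02)
            records.append(
                {
                    "accession": f"SYN{idx:05d}",
                    "label": f"synthetic {group} sp. {j + 1}",
                    "group": group,
                    "bases": bases,
                }
            )
            idx += 1
    return records
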